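"""Shared fixtures and independent brute-force oracles.

Oracles here deliberately use naive algorithms (explicit loops, dense
grid scans) so they stay independent of the library code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmcshell.core import Atom, MolecularSystem
from bmcshell.synthetic import RingSpec, make_facet, make_ring_channel


@pytest.fixture
def single_ring():
    """Ring of 12 atoms (vdW 1.5 A) at ring radius 5 A in z=0: analytic
    pore radius 3.5 A on the axis."""
    return make_ring_channel([RingSpec(0.0, 5.0, 12, 1.5)])


@pytest.fixture
def stacked_rings():
    """Rings of radii 6,5,4,5,6 A spaced 5 A apart along z (vdW 1.5):
    per-plane analytic pore radii 4.5, 3.5, 2.5, 3.5, 4.5."""
    radii = [6.0, 5.0, 4.0, 5.0, 6.0]
    return make_ring_channel(
        [RingSpec(z, r, 12, 1.5) for z, r in zip([-10, -5, 0, 5, 10], radii)]
    )


@pytest.fixture
def curved_facet():
    return make_facet(n_tiles=7, curvature_radius=200.0)


@pytest.fixture
def flat_facet():
    return make_facet(n_tiles=7, curvature_radius=np.inf)


def grid_search_radius(
    system: MolecularSystem,
    center0: np.ndarray,
    half_extent: float = 4.0,
    resolution: float = 0.05,
    axis_perp: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)),
) -> tuple[float, np.ndarray]:
    """Exhaustive in-plane grid search for the largest inscribed sphere.

    Scans a grid of the given resolution over the disk of radius
    ``half_extent`` in the plane through ``center0`` spanned by
    ``axis_perp`` and maximizes min_i(|c - x_i| - r_i) by direct
    evaluation. The disk domain matches the annealed search bound so the
    two methods optimize the identical problem.
    """
    e1, e2 = (np.asarray(v, dtype=float) for v in axis_perp)
    offs = np.arange(-half_extent, half_extent + resolution / 2, resolution)
    best_f, best_c = -np.inf, None
    pos = system.positions
    rad = system.vdw_radii
    for a in offs:
        sel = offs[offs**2 + a**2 <= half_extent**2]
        if len(sel) == 0:
            continue
        centers = center0 + a * e1 + sel[:, None] * e2
        d = np.sqrt(((centers[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
        f = (d - rad[None, :]).min(axis=1)
        k = int(np.argmax(f))
        if f[k] > best_f:
            best_f, best_c = float(f[k]), centers[k]
    return max(best_f, 0.0), best_c


def brute_force_water_contacts(
    frame: np.ndarray,
    system: MolecularSystem,
    residue: tuple,
    cutoff: float,
) -> int:
    """O(N^2) double loop over water residues and atoms, minimum image."""
    chain, resid = residue
    res_atoms = [
        i
        for i in range(system.n_atoms)
        if system.chain_ids[i] == chain and system.residue_ids[i] == resid
    ]
    box = system.box
    waters: dict[tuple, bool] = {}
    for i in range(system.n_atoms):
        if system.residue_names[i] not in {"HOH", "TIP3", "WAT", "SOL", "TIP3P"}:
            continue
        key = (system.chain_ids[i], int(system.residue_ids[i]))
        waters.setdefault(key, False)
        for j in res_atoms:
            delta = frame[i] - frame[j]
            if box is not None:
                for k in range(3):
                    delta[k] -= box[k] * round(delta[k] / box[k])
            if np.sqrt((delta**2).sum()) <= cutoff:
                waters[key] = True
                break
    return sum(waters.values())


def make_water_bath(
    n_waters: int, box: float, seed: int, protein_atoms: list[Atom] | None = None
) -> MolecularSystem:
    """Random single-site waters in a periodic cube, plus optional protein."""
    rng = np.random.default_rng(seed)
    atoms = list(protein_atoms or [])
    start = len(atoms)
    for w in range(n_waters):
        atoms.append(
            Atom(
                index=start + w,
                name="OH2",
                element="O",
                residue_id=w + 1,
                residue_name="TIP3",
                chain_id="W",
                position=rng.uniform(0, box, size=3),
                vdw_radius=1.52,
            )
        )
    return MolecularSystem(atoms, box=np.array([box, box, box]))
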