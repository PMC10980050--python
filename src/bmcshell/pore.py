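"""Channel pore-radius profiling by maximum inscribed spheres.

For each plane along a tile's channel axis the largest sphere that fits
without overlapping any atom's van der Waals sphere is found, its center
constrained to the slicing plane — the classic channel-profiling
construction. The in-plane search is a seeded Monte-Carlo anneal with a
deterministic simplex polish; successive slices are seeded from the
previous slice's optimized center (a guided walk along the channel), so
the profile follows the pore even where it is narrow or off-axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize

from .core import Atom, MolecularSystem, TileAssembly, Trajectory
from .geometry import _perp_unit, tile_center, tile_normal_of

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "InscribedSphere",
    "PoreProfile",
    "PoreEnvelope",
    "inscribed_radius",
    "profile_axis",
    "profile_pore",
    "bottleneck",
    "profile_trajectory",
]

DEFAULT_SEED = 2024


@dataclass(frozen=True)
class AnnealSchedule:
    """Monte-Carlo schedule for the in-plane sphere-center search.

    ``n_proposals`` Gaussian moves; step sigma and Metropolis temperature
    (both in Angstrom of radius) decay by ``decay`` every ``block``
    proposals. The anneal is followed by a deterministic Nelder-Mead
    polish of the best point found.
    """

    n_proposals: int = 1000
    sigma0: float = 0.5
    temp0: float = 0.1
    decay: float = 0.9
    block: int = 100
    polish: bool = True
    max_displacement: float = 15.0  # A, in-plane search bound about the seed


class InscribedSphere(NamedTuple):
    radius: float  # A, clamped at 0
    center: np.ndarray  # (3,)
    buried: bool  # True when no positive clearance was found


def _clearance_fn(positions: np.ndarray, radii: np.ndarray):
    def f(c: np.ndarray) -> float:
        d = np.linalg.norm(positions - c, axis=1) - radii
        return float(d.min())

    return f


def inscribed_radius(
    system: MolecularSystem,
    center0: np.ndarray,
    plane_normal: np.ndarray,
    seed: int | np.random.Generator = DEFAULT_SEED,
    schedule: AnnealSchedule = AnnealSchedule(),
    atom_mask: np.ndarray | None = None,
) -> InscribedSphere:
    """Largest sphere centered in a plane that avoids all atoms.

    Maximizes ``f(c) = min_i(|c - x_i| - r_i)`` over centers ``c`` in the
    plane through ``center0`` with normal ``plane_normal``. Returns the
    clamped-at-zero clearance, the optimized center, and a flag set when
    the plane point is sterically buried (no positive clearance found).

    ``atom_mask`` restricts the obstacle set (default: protein atoms,
    i.e. solvent and ions excluded).
    """
    if atom_mask is None:
        atom_mask = system.protein_mask()
    positions = system.positions[atom_mask]
    radii = system.vdw_radii[atom_mask]
    if len(positions) == 0:
        raise ValueError("no obstacle atoms selected")

    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    e1 = _perp_unit(n)
    e2 = np.cross(n, e1)
    c0 = np.asarray(center0, dtype=float)
    f3 = _clearance_fn(positions, radii)

    def f2(ab: np.ndarray) -> float:
        return f3(c0 + ab[0] * e1 + ab[1] * e2)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cur = np.zeros(2)
    f_cur = f2(cur)
    best, f_best = cur.copy(), f_cur
    sched = schedule
    bound = sched.max_displacement
    for k in range(sched.n_proposals):
        level = sched.decay ** (k // sched.block)
        prop = cur + rng.normal(0.0, sched.sigma0 * level, size=2)
        if np.linalg.norm(prop) > bound:
            continue
        f_prop = f2(prop)
        df = f_prop - f_cur
        if f_cur < 0:
            # buried walker: greedy climb only — tunnelling through the
            # atom wall into a different cavity is unphysical
            accept = df > 0
        else:
            accept = f_prop >= 0 and (
                df > 0 or rng.random() < np.exp(df / (sched.temp0 * level))
            )
        if accept:
            cur, f_cur = prop, f_prop
            if f_cur > f_best:
                best, f_best = cur.copy(), f_cur
    if sched.polish:
        def neg(ab: np.ndarray) -> float:
            if np.linalg.norm(ab) > bound:
                return 1e6 + np.linalg.norm(ab)
            return -f2(ab)

        res = minimize(
            neg,
            best,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
        )
        if -res.fun > f_best:
            best, f_best = res.x, -res.fun
    center = c0 + best[0] * e1 + best[1] * e2
    return InscribedSphere(
        radius=max(f_best, 0.0), center=center, buried=f_best <= 0.0
    )


@dataclass
class PoreProfile:
    """Pore radius along one channel axis for a single frame."""

    axis: np.ndarray  # unit vector
    anchor: np.ndarray  # point on the axis (z = 0), A
    z_values: np.ndarray  # strictly increasing, A
    radii: np.ndarray  # >= 0, A
    centers: np.ndarray  # (n, 3)
    buried: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if not (len(self.z_values) == len(self.radii) == len(self.centers)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.z_values) <= 0):
            raise ValueError("z_values must be strictly increasing")
        if np.any(self.radii < 0):
            raise ValueError("radii must be >= 0")
        if self.buried is None:
            self.buried = np.zeros(len(self.radii), dtype=bool)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"z": self.z_values, "radius": self.radii,
                             "buried": self.buried})

    def write_centers_pdb(self, path: str | Path) -> None:
        """Sphere centers as a pseudo-atom PDB for visualization."""
        from .io import write_structure

        atoms = [
            Atom(
                index=i,
                name="SPH",
                element="X",
                residue_id=i + 1,
                residue_name="SPH",
                chain_id="Z",
                position=self.centers[i],
                vdw_radius=max(float(self.radii[i]), 1e-3),
            )
            for i in range(len(self.radii))
        ]
        write_structure(MolecularSystem(atoms), path)


@dataclass
class PoreEnvelope:
    """Per-z min/mean/max pore radius pooled over frames and tiles."""

    z_values: np.ndarray
    r_min: np.ndarray
    r_mean: np.ndarray
    r_max: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if np.any(self.r_min > self.r_mean + 1e-12) or np.any(
            self.r_mean > self.r_max + 1e-12
        ):
            raise ValueError("envelope must satisfy r_min <= r_mean <= r_max")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z": self.z_values,
                "r_min": self.r_min,
                "r_mean": self.r_mean,
                "r_max": self.r_max,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def profile_axis(
    system: MolecularSystem,
    anchor: np.ndarray,
    axis: np.ndarray,
    z_range: tuple[float, float] = (-25.0, 25.0),
    step: float = 0.5,
    seed: int = DEFAULT_SEED,
    schedule: AnnealSchedule = AnnealSchedule(),
    atom_mask: np.ndarray | None = None,
) -> PoreProfile:
    """Pore-radius profile along an explicit axis through ``anchor``.

    z is the signed axial coordinate with 0 at the anchor. The walk
    starts at the slice nearest z=0 and proceeds outward in both
    directions, each slice seeded with the previous slice's optimized
    center stepped along the axis.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise ValueError(f"inverted z_range {z_range}")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    anchor = np.asarray(anchor, dtype=float)
    z_values = np.arange(z_lo, z_hi + 0.5 * step, step)

    n_z = len(z_values)
    radii = np.zeros(n_z)
    centers = np.zeros((n_z, 3))
    buried = np.zeros(n_z, dtype=bool)
    i0 = int(np.argmin(np.abs(z_values)))

    def run_slice(i: int, seed_center: np.ndarray) -> None:
        plane_pt = seed_center + (
            z_values[i] - np.dot(seed_center - anchor, axis)
        ) * axis  # project the walk seed into slice i's plane
        rng = np.random.default_rng([seed, i])
        sph = inscribed_radius(
            system, plane_pt, axis, seed=rng, schedule=schedule,
            atom_mask=atom_mask,
        )
        radii[i], centers[i], buried[i] = sph.radius, sph.center, sph.buried

    run_slice(i0, anchor + z_values[i0] * axis)
    for i in range(i0 + 1, n_z):
        run_slice(i, centers[i - 1])
    for i in range(i0 - 1, -1, -1):
        run_slice(i, centers[i + 1])
    return PoreProfile(
        axis=axis, anchor=anchor, z_values=z_values, radii=radii,
        centers=centers, buried=buried,
    )


def profile_pore(
    system: MolecularSystem,
    assembly: TileAssembly,
    tile_id: str,
    z_range: tuple[float, float] = (-25.0, 25.0),
    step: float = 0.5,
    seed: int = DEFAULT_SEED,
    schedule: AnnealSchedule = AnnealSchedule(),
    atom_mask: np.ndarray | None = None,
) -> PoreProfile:
    """Pore-radius profile along one tile's channel axis.

    The axis is the tile's oriented pore normal through its pore center;
    z is signed with 0 at the pore center. See :func:`profile_axis` for
    the guided-walk details.
    """
    axis = tile_normal_of(system, assembly, tile_id)
    anchor = tile_center(system, assembly, tile_id)
    return profile_axis(
        system, anchor, axis, z_range=z_range, step=step, seed=seed,
        schedule=schedule, atom_mask=atom_mask,
    )


def bottleneck(profile: PoreProfile) -> tuple[float, float, float]:
    """(z, radius, diameter) of the narrowest point of a profile.

    Ties are broken toward the smallest ``|z|`` (then the more negative z).
    """
    if len(profile.radii) == 0:
        raise ValueError("empty profile")
    order = sorted(
        range(len(profile.radii)),
        key=lambda i: (profile.radii[i], abs(profile.z_values[i]), profile.z_values[i]),
    )
    i = order[0]
    r = float(profile.radii[i])
    return float(profile.z_values[i]), r, 2.0 * r


def profile_trajectory(
    traj: Trajectory,
    assembly: TileAssembly,
    tile_kind: str,
    z_range: tuple[float, float] = (-25.0, 25.0),
    step: float = 0.5,
    stride: int = 1,
    seed: int = DEFAULT_SEED,
    schedule: AnnealSchedule = AnnealSchedule(),
):
    """Envelope and per-tile bottleneck series over a trajectory.

    Pools per-z statistics over all frames (every ``stride``-th) and all
    tiles of ``tile_kind`` ("hexamer", "trimer_upper", "trimer_lower", or
    "trimer" for both stacked trimers). Returns ``(PoreEnvelope,
    bottleneck_series)`` where the series maps tile_id to a DataFrame
    with per-frame (time, z, radius, diameter).
    """
    import pandas as pd

    tiles = assembly.tiles_of_kind(tile_kind)
    if not tiles:
        raise ValueError(f"no tiles of kind {tile_kind!r}")
    if stride >= traj.n_frames:
        if stride > traj.n_frames:
            logger.warning(
                "stride %d exceeds trajectory length %d; using first frame only",
                stride, traj.n_frames,
            )
        frame_ids = [0]
    else:
        frame_ids = list(range(0, traj.n_frames, stride))

    all_radii = []
    z_ref = None
    series: dict[str, "pd.DataFrame"] = {}
    for tile in tiles:
        rows = []
        for fi in frame_ids:
            frame = traj.frame_system(fi)
            prof = profile_pore(
                frame, assembly, tile.tile_id, z_range=z_range, step=step,
                seed=seed, schedule=schedule,
            )
            if z_ref is None:
                z_ref = prof.z_values
            all_radii.append(prof.radii)
            z_b, r_b, d_b = bottleneck(prof)
            rows.append(
                {"frame": fi, "time": fi * traj.dt, "z": z_b,
                 "radius": r_b, "diameter": d_b}
            )
        series[tile.tile_id] = pd.DataFrame(rows)
    stacked = np.asarray(all_radii)
    envelope = PoreEnvelope(
        z_values=z_ref,
        r_min=stacked.min(axis=0),
        r_mean=stacked.mean(axis=0),
        r_max=stacked.max(axis=0),
        n_frames=len(frame_ids),
    )
    return envelope, series
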