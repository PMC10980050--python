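"""Synthetic test systems with known ground truth.

Every pipeline stage can be exercised without any experimental download:
pseudo-atom ring channels whose pore radius is analytic, curved or flat
multi-tile facets of pseudo-hexamers, scripted hydration trajectories
whose residence events are known exactly, breathing channels with known
radius envelopes, and exponential dose-response curves with known rate.

All generators are deterministic under a fixed seed. These fixtures make
no claim of physical realism — pseudo-atoms stand in for residues, and
water motion is scripted, not dynamical; what they guarantee is an exact
or analytic ground truth for each measurement.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Atom, MolecularSystem, Tile, TileAssembly, Trajectory
from .hydration import ResidenceEvent
from .xfms import DEFAULT_EXPOSURES, DoseResponse

__all__ = [
    "RingSpec",
    "make_ring_channel",
    "ring_tile_assembly",
    "make_facet",
    "make_sheet_unit",
    "make_hydration_trajectory",
    "make_breathing_channel",
    "make_breathing_tile",
    "make_random_cage",
    "make_dose_response",
    "write_ground_truth_events",
]

_CHAIN_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class RingSpec:
    """One ring of pseudo-atoms: ring of ``n_atoms`` at ``ring_radius``
    from the z-axis in the plane at ``z``, each with radius ``vdw``."""

    z: float
    ring_radius: float
    n_atoms: int
    vdw: float


def _ring_atoms(
    spec: RingSpec, start_index: int, residue_id: int, n_chains: int = 1,
    phase: float = 0.0,
) -> list[Atom]:
    ang = phase + 2.0 * np.pi * np.arange(spec.n_atoms) / spec.n_atoms
    sector = 2.0 * np.pi / n_chains
    return [
        Atom(
            index=start_index + j,
            name="C",
            element="C",
            residue_id=residue_id,
            residue_name="RNG",
            chain_id=_CHAIN_POOL[int((a % (2.0 * np.pi)) // sector) % n_chains],
            position=np.array(
                [spec.ring_radius * np.cos(a), spec.ring_radius * np.sin(a), spec.z]
            ),
            vdw_radius=spec.vdw,
        )
        for j, a in enumerate(ang)
    ]


def make_ring_channel(
    channel_spec: Sequence[RingSpec | tuple],
    allow_closed: bool = False,
    n_chains: int = 1,
) -> MolecularSystem:
    """Stacked pseudo-atom rings centered on the z-axis.

    The analytic pore radius in each ring plane is
    ``ring_radius - vdw``. A ring with ``ring_radius <= vdw`` is a
    closed pore (the trimer channel of the cryo-EM start is effectively
    closed) and must be requested explicitly with ``allow_closed``.
    With ``n_chains`` > 1 atoms are split into angular-sector chains so
    the rings can be declared a tile (see :func:`ring_tile_assembly`).
    """
    specs = [s if isinstance(s, RingSpec) else RingSpec(*s) for s in channel_spec]
    if not specs:
        raise ValueError("need at least one ring")
    atoms: list[Atom] = []
    for ri, spec in enumerate(specs):
        if spec.ring_radius <= spec.vdw and not allow_closed:
            raise ValueError(
                f"ring at z={spec.z} has ring_radius {spec.ring_radius} <= vdw "
                f"{spec.vdw} (closed pore); pass allow_closed=True if intended"
            )
        atoms.extend(
            _ring_atoms(spec, len(atoms), residue_id=ri + 1, n_chains=n_chains)
        )
    return MolecularSystem(atoms)


def ring_tile_assembly(kind: str = "hexamer") -> TileAssembly:
    """Declare a 6-chain (or 3-chain trimer) ring channel as one tile."""
    n = 6 if kind == "hexamer" else 3
    return TileAssembly(
        tiles=[Tile(tile_id="ring", kind=kind, chain_ids=tuple(_CHAIN_POOL[:n]))]
    )


# ---------------------------------------------------------------------------
# facets


def _tile_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis transported from the global frame along z->direction."""
    from .geometry import align_to_axis

    z = np.array([0.0, 0.0, 1.0])
    R = align_to_axis(z, direction).rotation
    return R @ np.array([1.0, 0.0, 0.0]), R @ np.array([0.0, 1.0, 0.0])


def _pseudo_tile_atoms(
    center: np.ndarray,
    normal: np.ndarray,
    chains: Sequence[str],
    tile_radius: float,
    beads_per_chain: int,
    vdw: float,
    start_index: int,
) -> list[Atom]:
    """One pseudo-tile: each chain is a bead arc in its angular sector."""
    e1, e2 = _tile_frame(normal)
    n_chains = len(chains)
    sector = 2.0 * np.pi / n_chains
    atoms: list[Atom] = []
    idx = start_index
    for ci, chain in enumerate(chains):
        base = ci * sector
        for b in range(beads_per_chain):
            frac = (b + 0.5) / beads_per_chain
            a = base + frac * sector
            # beads alternate between the rim and slightly inward so each
            # chain has some radial extent
            r = tile_radius * (1.0 if b % 2 == 0 else 0.8)
            local = r * (np.cos(a) * e1 + np.sin(a) * e2)
            atoms.append(
                Atom(
                    index=idx,
                    name="CA",
                    element="C",
                    residue_id=b + 1,
                    residue_name="GLY",
                    chain_id=chain,
                    position=center + local,
                    vdw_radius=vdw,
                )
            )
            idx += 1
    return atoms


def make_facet(
    n_tiles: int = 7,
    curvature_radius: float = math.inf,
    spacing: float = 26.0,
    tile_radius: float = 12.0,
    beads_per_chain: int = 5,
    vdw: float = 1.5,
    central_trimer: bool = False,
    stacked_trimer: bool = False,
    trimer_gap: float = 8.0,
) -> tuple[MolecularSystem, TileAssembly]:
    """Pseudo-hexamer facet on a spherical cap (or plane at infinity).

    The central tile sits at the origin with normal +z; the remaining
    ``n_tiles - 1`` tiles surround it at arc distance ``spacing`` on the
    sphere of radius ``curvature_radius``, with radial (outward) normals.
    With ``central_trimer`` the central tile is a trimer (optionally a
    stacked pair with the lower copy ``trimer_gap`` A beneath), matching
    the one-trimer-surrounded-by-hexamers shell-fragment layout.
    """
    if n_tiles < 1:
        raise ValueError("need at least one tile")
    flat = math.isinf(curvature_radius)
    R = curvature_radius
    z = np.array([0.0, 0.0, 1.0])
    S = np.array([0.0, 0.0, -R]) if not flat else None

    # tile sites: center + hexagonal ring(s)
    offsets = [np.zeros(2)]
    ring = 1
    while len(offsets) < n_tiles:
        for k in range(6 * ring):
            a = 2.0 * np.pi * k / (6 * ring)
            offsets.append(ring * spacing * np.array([np.cos(a), np.sin(a)]))
            if len(offsets) == n_tiles:
                break
        ring += 1

    tiles: list[Tile] = []
    atoms: list[Atom] = []
    chain_cursor = 0

    def next_chains(n: int) -> list[str]:
        nonlocal chain_cursor
        if chain_cursor + n > len(_CHAIN_POOL):
            raise ValueError("too many tiles for single-character chain ids")
        out = list(_CHAIN_POOL[chain_cursor : chain_cursor + n])
        chain_cursor += n
        return out

    for ti, off in enumerate(offsets):
        d = np.linalg.norm(off)
        if flat or d == 0:
            normal = z.copy()
            center = np.array([off[0], off[1], 0.0])
            if not flat:
                center = np.zeros(3)
        else:
            theta = d / R  # arc length -> polar angle
            dhat = np.array([off[0], off[1], 0.0]) / d
            normal = math.cos(theta) * z + math.sin(theta) * dhat
            center = S + R * normal
        is_trimer = central_trimer and ti == 0
        if is_trimer:
            chains = next_chains(3)
            kind = "trimer_upper"
        else:
            chains = next_chains(6)
            kind = "hexamer"
        tile_id = f"T{ti}"
        tiles.append(Tile(tile_id=tile_id, kind=kind, chain_ids=tuple(chains)))
        atoms.extend(
            _pseudo_tile_atoms(
                center, normal, chains, tile_radius, beads_per_chain, vdw,
                len(atoms),
            )
        )
        if is_trimer and stacked_trimer:
            chains_lo = next_chains(3)
            tiles.append(
                Tile(tile_id=f"T{ti}_lower", kind="trimer_lower",
                     chain_ids=tuple(chains_lo))
            )
            atoms.extend(
                _pseudo_tile_atoms(
                    center - trimer_gap * normal, normal, chains_lo,
                    tile_radius, beads_per_chain, vdw, len(atoms),
                )
            )
    return MolecularSystem(atoms), TileAssembly(tiles=tiles)


def make_sheet_unit(
    spacing: float = 26.0,
    tile_radius: float = 12.0,
    beads_per_chain: int = 5,
    vdw: float = 1.5,
    trimer_gap: float = 8.0,
) -> tuple[MolecularSystem, TileAssembly]:
    """Flat periodic sheet motif: three hexamers plus one stacked trimer.

    The trimer pair sits at the origin with three hexamers at lattice
    sites of a hexagonal lattice with spacing ``spacing``; under the
    2a x sqrt(3)a rectangular cell this motif tiles the plane with every
    trimer surrounded by hexamers.
    """
    a = spacing
    h = a * math.sqrt(3.0) / 2.0
    sites = [
        ("trimer", np.array([0.0, 0.0, 0.0])),
        ("hexamer", np.array([a, 0.0, 0.0])),
        ("hexamer", np.array([a / 2.0, h, 0.0])),
        ("hexamer", np.array([3.0 * a / 2.0, h, 0.0])),
    ]
    z = np.array([0.0, 0.0, 1.0])
    atoms: list[Atom] = []
    tiles: list[Tile] = []
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = list(_CHAIN_POOL[cursor : cursor + n])
        cursor += n
        return out

    for ti, (kind, center) in enumerate(sites):
        if kind == "trimer":
            for sub, (label, offset) in enumerate(
                [("trimer_upper", np.zeros(3)), ("trimer_lower", -trimer_gap * z)]
            ):
                chains = take(3)
                tiles.append(
                    Tile(tile_id=f"T{ti}_{label}", kind=label,
                         chain_ids=tuple(chains))
                )
                atoms.extend(
                    _pseudo_tile_atoms(
                        center + offset, z, chains, tile_radius,
                        beads_per_chain, vdw, len(atoms),
                    )
                )
        else:
            chains = take(6)
            tiles.append(
                Tile(tile_id=f"T{ti}", kind="hexamer", chain_ids=tuple(chains))
            )
            atoms.extend(
                _pseudo_tile_atoms(
                    center, z, chains, tile_radius, beads_per_chain, vdw,
                    len(atoms),
                )
            )
    return MolecularSystem(atoms), TileAssembly(tiles=tiles)


# ---------------------------------------------------------------------------
# scripted hydration trajectories


def make_hydration_trajectory(
    mean_dwell_ns: float = 30.0,
    n_waters: int = 30,
    n_frames: int = 900,
    dt: float = 1.0,
    seed: int = 0,
    dwell_distance: float = 3.0,
    far_distance: float = 20.0,
) -> tuple[Trajectory, list[ResidenceEvent]]:
    """Scripted approach-dwell-escape water excursions with known events.

    One target residue (chain "A", resid 1) sits at the origin; each
    water alternates between a far position (``far_distance`` A, well
    beyond the 8 A exit cutoff) and a dwell position (``dwell_distance``
    A, within the 5 A entry cutoff). Dwell durations are drawn from an
    exponential law with mean ``mean_dwell_ns``, discretized to whole
    frames (minimum 1); waters jump between shells in a single frame, so
    scripted distances never linger in the (5, 8] hysteresis band at an
    entry or exit. Returns the trajectory and the exact event list (all
    events close before the final frame; none are censored).

    A dwell that would cross the final frame is not scheduled, which
    length-biases the realized durations slightly short; the default
    window (900 frames = 30x the default dwell time) keeps that edge
    effect under ~2 percent of the mean.
    """
    if mean_dwell_ns <= 0 or n_waters < 0 or n_frames < 2:
        raise ValueError("bad dwell specification")
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    for j, delta in enumerate(
        [np.zeros(3), np.array([0.4, 0, 0]), np.array([0, 0.4, 0])]
    ):
        atoms.append(
            Atom(index=j, name=f"C{j}", element="C", residue_id=1,
                 residue_name="GLY", chain_id="A", position=delta,
                 vdw_radius=1.7)
        )
    for w in range(n_waters):
        atoms.append(
            Atom(index=3 + w, name="OH2", element="O", residue_id=w + 1,
                 residue_name="TIP3", chain_id="W",
                 position=np.array([far_distance, 0.0, 0.0]),
                 vdw_radius=1.52)
        )
    topology = MolecularSystem(atoms)

    frames = np.empty((n_frames, len(atoms), 3))
    frames[:, :3, :] = topology.positions[:3]
    mean_dwell_frames = mean_dwell_ns / dt
    events: list[ResidenceEvent] = []
    for w in range(n_waters):
        ai = 3 + w
        sched = np.zeros(n_frames, dtype=bool)  # True while dwelling
        fi = int(rng.integers(1, 6))
        while fi < n_frames - 1:
            d = max(1, int(round(rng.exponential(mean_dwell_frames))))
            if fi + d > n_frames - 1:
                break  # would not close before the final frame; skip
            sched[fi : fi + d] = True
            events.append(ResidenceEvent(("W", w + 1), fi, d, False))
            fi += d + int(rng.integers(1, 6))
        u_dwell = _random_unit(rng)
        u_far = _random_unit(rng)
        for f in range(n_frames):
            r = dwell_distance if sched[f] else far_distance
            u = u_dwell if sched[f] else u_far
            frames[f, ai] = r * u
    events.sort(key=lambda e: (e.start_frame, e.water_id))
    return Trajectory(topology=topology, frames=frames, dt=dt), events


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def write_ground_truth_events(
    events: Iterable[ResidenceEvent], path: str | Path
) -> None:
    """JSON sidecar with the scripted residence events."""
    payload = [
        {"water": list(e.water_id), "start_frame": e.start_frame,
         "duration_frames": e.duration_frames, "censored": e.censored}
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# breathing channels and tiles


def make_breathing_channel(
    base_radius: float = 5.0,
    amplitude: float = 1.0,
    n_frames: int = 8,
    period_frames: int = 4,
    n_ring_atoms: int = 16,
    vdw: float = 1.5,
    dt: float = 1.0,
    z_planes: Sequence[float] = (-4.0, 0.0, 4.0),
    n_chains: int = 1,
) -> Trajectory:
    """Ring channel whose radius oscillates sinusoidally frame to frame.

    Ring radius at frame f is ``base + amplitude * sin(2 pi f / period)``;
    with ``period_frames`` dividing 4 the extreme radii are sampled
    exactly, so the analytic envelope bounds are
    ``base -/+ amplitude - vdw``.
    """
    specs = [RingSpec(z, base_radius, n_ring_atoms, vdw) for z in z_planes]
    topology = make_ring_channel(specs, n_chains=n_chains)
    frames = np.empty((n_frames, topology.n_atoms, 3))
    for f in range(n_frames):
        r = base_radius + amplitude * math.sin(2.0 * math.pi * f / period_frames)
        scale = r / base_radius
        pos = topology.positions.copy()
        pos[:, :2] *= scale
        frames[f] = pos
    return Trajectory(topology=topology, frames=frames, dt=dt)


def make_breathing_tile(
    scales: Sequence[float] = (1.0, 1.02, 0.98, 1.05),
    dt: float = 1.0,
    **facet_kwargs,
) -> tuple[Trajectory, TileAssembly, np.ndarray]:
    """Single flat pseudo-hexamer breathing radially about its centroid.

    Frame f scales the tile's centered coordinates by ``scales[f]``; the
    least-squares-superposed C-alpha RMSD against the unscaled reference
    is then analytically ``|scale - 1| * rms(centered coords)``. Returns
    (trajectory, assembly, analytic per-frame rmsd).
    """
    system, assembly = make_facet(n_tiles=1, **facet_kwargs)
    center = system.positions.mean(axis=0)
    centered = system.positions - center
    rms = math.sqrt(float((centered**2).sum() / len(centered)))
    frames = np.array([center + s * centered for s in scales])
    analytic = np.array([abs(s - 1.0) * rms for s in scales])
    return (
        Trajectory(topology=system, frames=frames, dt=dt),
        assembly,
        analytic,
    )


def make_random_cage(
    n_atoms: int = 50,
    seed: int | np.random.Generator = 0,
    shell_radius: float = 6.0,
    jitter: float = 1.5,
    vdw_range: tuple[float, float] = (1.2, 1.9),
) -> MolecularSystem:
    """Random pseudo-atom cage around the origin (pore-oracle fixture).

    Atoms are scattered on a jittered sphere so the origin region stays
    open; van der Waals radii vary atom to atom.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    atoms = []
    for i in range(n_atoms):
        u = _random_unit(rng)
        r = shell_radius + rng.uniform(-jitter, jitter)
        atoms.append(
            Atom(index=i, name="C", element="C", residue_id=i + 1,
                 residue_name="CAG", chain_id="A", position=r * u,
                 vdw_radius=float(rng.uniform(*vdw_range)))
        )
    return MolecularSystem(atoms)


# ---------------------------------------------------------------------------
# dose-response curves


def make_dose_response(
    k_values: Mapping[str, float],
    exposures: np.ndarray = DEFAULT_EXPOSURES,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, DoseResponse]:
    """Exponential dose-response curves with multiplicative noise.

    F(t) = exp(-k t) * (1 + eps), eps ~ Normal(0, noise_sd), clamped to
    [0, 1]. The default exposure schedule is 0-2000 s in 7 steps.
    """
    rng = np.random.default_rng(seed)
    exposures = np.asarray(exposures, dtype=float)
    out: dict[str, DoseResponse] = {}
    for label, k in k_values.items():
        f = np.exp(-k * exposures)
        if noise_sd > 0:
            f = f * (1.0 + rng.normal(0.0, noise_sd, size=len(exposures)))
        f = np.clip(f, 0.0, 1.0)
        out[label] = DoseResponse(
            residue_label=label, exposures=exposures, fraction_unmodified=f
        )
    return out
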