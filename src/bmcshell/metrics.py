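"""Structural stability and accessibility metrics.

Per-tile C-alpha RMSD against a shared reference tile (least-squares
superposition per frame, so only internal deformation is scored), and
residue-wise solvent-accessible surface area by the Shrake-Rupley
rolling-probe construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import MolecularSystem, RigidTransform, TileAssembly, Trajectory

__all__ = [
    "RMSDSeries",
    "superpose",
    "rmsd_series",
    "sasa_per_residue",
    "sasa_trajectory_mean",
]


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of two matched point sets.

    Kabsch algorithm with the proper-rotation correction: returns the
    transform carrying ``mobile`` onto ``reference`` and the RMSD after
    applying it.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (rank-deficient) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum() / n))
    return transform, rmsd


@dataclass
class RMSDSeries:
    """Per-frame superposed RMSD of one tile versus a reference tile."""

    tile_id: str
    times: np.ndarray  # ns
    rmsd: np.ndarray  # A
    reference_id: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if len(self.times) != len(self.rmsd):
            raise ValueError("times and rmsd must have equal length")
        if np.any(self.rmsd < 0):
            raise ValueError("rmsd must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tile_id": self.tile_id, "time_ns": self.times, "rmsd": self.rmsd}
        )


def _tile_ca_coords(
    system: MolecularSystem, assembly: TileAssembly, tile_id: str
) -> np.ndarray:
    mask = assembly.tile_mask(system, tile_id) & (system.names == "CA")
    if not mask.any():
        mask = assembly.tile_mask(system, tile_id)
    return system.positions[mask], mask


def rmsd_series(
    traj: Trajectory,
    assembly: TileAssembly,
    reference: MolecularSystem,
    reference_assembly: TileAssembly | None = None,
    reference_tile: str | None = None,
) -> list[RMSDSeries]:
    """C-alpha RMSD of every tile against one shared reference tile.

    Each frame's tile is superposed onto the reference tile before the
    RMSD is taken, so global drift does not register. The reference tile
    defaults to the first tile of the reference assembly (which defaults
    to ``assembly`` — i.e. the reference structure shares the topology).
    Tiles whose C-alpha count differs from the reference raise with the
    offending tile named.
    """
    ref_assembly = reference_assembly or assembly
    ref_tile_id = reference_tile or ref_assembly.tiles[0].tile_id
    ref_coords, _ = _tile_ca_coords(reference, ref_assembly, ref_tile_id)

    out: list[RMSDSeries] = []
    for tile in assembly.tiles:
        mask = assembly.tile_mask(traj.topology, tile.tile_id) & (
            traj.topology.names == "CA"
        )
        if not mask.any():
            mask = assembly.tile_mask(traj.topology, tile.tile_id)
        if mask.sum() != len(ref_coords):
            raise ValueError(
                f"tile {tile.tile_id!r} has {int(mask.sum())} C-alpha atoms but "
                f"reference tile {ref_tile_id!r} has {len(ref_coords)}"
            )
        vals = np.empty(traj.n_frames)
        for fi in range(traj.n_frames):
            _, vals[fi] = superpose(traj.frames[fi][mask], ref_coords)
        out.append(
            RMSDSeries(
                tile_id=tile.tile_id,
                times=traj.times,
                rmsd=vals,
                reference_id=ref_tile_id,
            )
        )
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_per_residue(
    frame: np.ndarray,
    system: MolecularSystem,
    probe_radius: float = 1.4,
    n_points: int = 960,
    context_mask: np.ndarray | None = None,
    target_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Residue-wise solvent-accessible surface area (Shrake-Rupley).

    Every atom's sphere of radius vdW + probe is sampled with
    ``n_points`` quasi-uniform points; a point is exposed iff it lies
    outside every other context atom's expanded sphere. Residue area is
    the sum over its atoms. ``context_mask`` selects the occluding atoms
    (default: all protein atoms — waters and ions never occlude);
    ``target_mask`` restricts which atoms are scored (default: the
    context). Returns a DataFrame keyed by (chain_id, residue_id,
    residue_name) with an ``area`` column in A^2.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable quadrature")
    if context_mask is None:
        context_mask = system.protein_mask()
    if target_mask is None:
        target_mask = context_mask
    frame = np.asarray(frame, dtype=float)

    ctx_idx = np.flatnonzero(context_mask)
    ctx_pos = frame[ctx_idx]
    ctx_rad = system.vdw_radii[ctx_idx] + probe_radius
    tree = cKDTree(ctx_pos)
    max_rad = ctx_rad.max() if len(ctx_rad) else 0.0
    sphere = _fibonacci_sphere(n_points)

    pos_in_ctx = {int(g): k for k, g in enumerate(ctx_idx)}
    areas: dict[tuple[str, int, str], float] = {}
    for i in np.flatnonzero(target_mask):
        ri = system.vdw_radii[i] + probe_radius
        pts = frame[i] + ri * sphere
        neigh = tree.query_ball_point(frame[i], ri + max_rad)
        self_k = pos_in_ctx.get(int(i))
        neigh = [k for k in neigh if k != self_k]
        exposed = np.ones(n_points, dtype=bool)
        for k in neigh:
            d2 = ((pts - ctx_pos[k]) ** 2).sum(axis=1)
            exposed &= d2 > ctx_rad[k] ** 2
            if not exposed.any():
                break
        area = 4.0 * np.pi * ri**2 * exposed.sum() / n_points
        key = (
            system.chain_ids[i],
            int(system.residue_ids[i]),
            system.residue_names[i],
        )
        areas[key] = areas.get(key, 0.0) + area

    rows = [
        {"chain_id": ch, "residue_id": rid, "residue_name": rn, "area": a}
        for (ch, rid, rn), a in sorted(areas.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["probe_radius"] = probe_radius
    df.attrs["n_points"] = n_points
    return df


def sasa_trajectory_mean(
    traj: Trajectory,
    assembly: TileAssembly,
    class_filter: str = "all",
    probe_radius: float = 1.4,
    n_points: int = 960,
    stride: int = 1,
) -> pd.DataFrame:
    """Trajectory-mean residue SASA pooled over hexamer monomers of a class.

    Returns a DataFrame keyed by (residue_id, residue_name) with the area
    averaged over frames (every ``stride``-th) and over the selected
    monomers, aligned by residue number.
    """
    system = traj.topology
    chains = assembly.chains_in_class(class_filter)
    if not chains:
        raise ValueError(f"no hexamer monomer passes class filter {class_filter!r}")
    target_mask = np.isin(system.chain_ids, chains) & system.protein_mask()
    frame_ids = list(range(0, traj.n_frames, max(stride, 1)))
    acc: dict[tuple[int, str], list[float]] = {}
    for fi in frame_ids:
        df = sasa_per_residue(
            traj.frames[fi], system, probe_radius, n_points,
            target_mask=target_mask,
        )
        for _, row in df.iterrows():
            acc.setdefault(
                (int(row.residue_id), row.residue_name), []
            ).append(float(row.area))
    rows = [
        {
            "residue_id": rid,
            "residue_name": rn,
            "area": float(np.mean(v)),
            "class": class_filter,
        }
        for (rid, rn), v in sorted(acc.items())
    ]
    out = pd.DataFrame(rows)
    out.attrs["probe_radius"] = probe_radius
    out.attrs["n_frames"] = len(frame_ids)
    out.attrs["n_monomers_averaged"] = len(chains)
    return out
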