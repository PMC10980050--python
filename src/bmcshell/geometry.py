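"""Rigid-body geometry for shell facets.

Builds planar sheet models from curved shell facets: per-tile pore
normals (cross product of in-plane vectors between adjacent chains),
minimal rotations onto a target axis, per-tile rigid flattening with
in-plane placement by gnomonic projection from the facet's best-fit
sphere, inference of an orthorhombic periodic cell from tile spacing,
and Gaussian synthetic density maps used as flexible-fitting targets.

Flattening is strictly rigid per tile: internal relaxation of each tile
into the target density is delegated to external flexible-fitting tools
and is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core import MolecularSystem, RigidTransform, TileAssembly

__all__ = [
    "DensityGrid",
    "tile_reference_points",
    "tile_normal",
    "tile_normal_of",
    "tile_center",
    "align_to_axis",
    "flatten_facet",
    "build_periodic_unit",
    "synthetic_density",
]

_COLLINEAR_TOL = 1e-6


# ---------------------------------------------------------------------------
# pore normals


def tile_reference_points(
    system: MolecularSystem, assembly: TileAssembly, tile_id: str
) -> np.ndarray:
    """Per-chain reference points of a tile, ordered around the pore.

    Each chain contributes the centroid of its C-alpha atoms (all atoms
    when the chain has none); points are sorted by angle about the tile
    centroid in the tile's best-fit plane, so consecutive points are
    adjacent chains.
    """
    tile = assembly.tile(tile_id)
    pts = []
    for ch in tile.chain_ids:
        mask = system.chain_mask(ch)
        ca = mask & (system.names == "CA")
        sel = ca if ca.any() else mask
        pts.append(system.positions[sel].mean(axis=0))
    pts = np.asarray(pts)
    center = pts.mean(axis=0)
    centered = pts - center
    # best-fit plane normal = left-singular vector of smallest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n = vt[-1]
    e1 = centered[0] - np.dot(centered[0], n) * n
    if np.linalg.norm(e1) < 1e-12:
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    ang = np.arctan2(centered @ e2, centered @ e1)
    return pts[np.argsort(ang)]


def tile_normal(
    tile_coords: np.ndarray, assembly_centroid: np.ndarray | None = None
) -> np.ndarray:
    """Unit normal of a tile pore from ordered per-chain reference points.

    The normal is the (normalized) sum of cross products of vectors from
    the tile centroid to consecutive reference points — for three points
    this is exactly v1 x v2 of the two adjacent-pair vectors. When
    ``assembly_centroid`` is given, the sign is fixed so the normal points
    away from it.
    """
    pts = np.asarray(tile_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 reference points of dimension 3")
    center = pts.mean(axis=0)
    c = pts - center
    n = np.cross(c, np.roll(c, -1, axis=0)).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < _COLLINEAR_TOL:
        raise ValueError("reference points are collinear; pore normal undefined")
    n /= norm
    outward = None
    if assembly_centroid is not None:
        outward = center - np.asarray(assembly_centroid, dtype=float)
    if outward is not None and abs(np.dot(n, outward)) > 1e-6 * max(
        np.linalg.norm(outward), 1.0
    ):
        if np.dot(n, outward) < 0:
            n = -n
    else:
        # outwardness undefined (no centroid, or tile center coincides with
        # it — e.g. a flat sheet): canonical sign, largest component positive
        k = int(np.argmax(np.abs(n)))
        if n[k] < 0:
            n = -n
    return n


def tile_center(
    system: MolecularSystem, assembly: TileAssembly, tile_id: str
) -> np.ndarray:
    """Pore center of a tile: centroid of its per-chain reference points."""
    return tile_reference_points(system, assembly, tile_id).mean(axis=0)


def tile_normal_of(
    system: MolecularSystem,
    assembly: TileAssembly,
    tile_id: str,
    assembly_centroid: np.ndarray | None = None,
) -> np.ndarray:
    """Oriented pore normal of one tile of an assembly."""
    if assembly_centroid is None:
        centers = [tile_center(system, assembly, t.tile_id) for t in assembly.tiles]
        assembly_centroid = np.mean(centers, axis=0)
    pts = tile_reference_points(system, assembly, tile_id)
    return tile_normal(pts, assembly_centroid=assembly_centroid)


# ---------------------------------------------------------------------------
# rotations


def align_to_axis(normal: np.ndarray, target_axis: np.ndarray) -> RigidTransform:
    """Minimal rotation carrying ``normal`` onto ``target_axis``.

    Both inputs must be unit vectors. The rotation axis is
    normal x target_axis; antiparallel inputs rotate by pi about the
    lowest-index coordinate axis not parallel to ``normal`` (projected
    perpendicular), a deterministic convention.
    """
    n = np.asarray(normal, dtype=float)
    t = np.asarray(target_axis, dtype=float)
    for v, nm in ((n, "normal"), (t, "target_axis")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError(f"{nm} must be unit length")
    c = float(np.dot(n, t))
    axis = np.cross(n, t)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return RigidTransform.identity()
        # antiparallel: pi about a canonical perpendicular
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            perp = e - np.dot(e, n) * n
            if np.linalg.norm(perp) > 1e-6:
                axis = perp / np.linalg.norm(perp)
                break
        R = 2.0 * np.outer(axis, axis) - np.eye(3)
        return RigidTransform(R, np.zeros(3))
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    R = np.eye(3) + s * K + (1.0 - c) * (K @ K)
    return RigidTransform(R, np.zeros(3))


# ---------------------------------------------------------------------------
# flattening


def _consistent_normals(
    system: MolecularSystem, assembly: TileAssembly
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Tile centers and normals with a consistent outward orientation."""
    centers = [tile_center(system, assembly, t.tile_id) for t in assembly.tiles]
    raw = [
        tile_normal(tile_reference_points(system, assembly, t.tile_id))
        for t in assembly.tiles
    ]
    normals = [raw[0]]
    for n in raw[1:]:
        normals.append(n if np.dot(n, normals[0]) >= 0 else -n)
    # orient outward (away from assembly centroid) when that is well defined
    ac = np.mean(centers, axis=0)
    score = sum(np.dot(n, c - ac) for n, c in zip(normals, centers))
    if score < -1e-9:
        normals = [-n for n in normals]
    return centers, normals


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through points; (center, radius)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = math.sqrt(max(sol[3] + center @ center, 0.0))
    return center, radius


def _min_intertile_distance(
    positions: np.ndarray, masks: list[np.ndarray]
) -> float:
    dmin = np.inf
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            d = cdist(positions[masks[i]], positions[masks[j]]).min()
            dmin = min(dmin, d)
    return float(dmin)


def _nn_spacing(centers: np.ndarray) -> float:
    d = cdist(centers, centers)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def flatten_facet(
    system: MolecularSystem,
    assembly: TileAssembly,
    target_axis: np.ndarray = np.array([0.0, 0.0, 1.0]),
    overlap_tolerance: float = 1.0,
) -> MolecularSystem:
    """Rigidly flatten a curved facet so every tile normal hits one axis.

    Each tile is rotated as a rigid body about its own pore center by the
    minimal rotation taking its normal to ``target_axis``; the reference
    tile (first trimer, else the most central tile) lands at the origin.
    In-plane positions come from gnomonic projection of tile centers from
    the facet's best-fit sphere, rescaled so the mean nearest-neighbor
    tile spacing matches the input; radial offsets (e.g. the two stacked
    trimers) become offsets along the target axis. A planar input is a
    fixed point up to one global rigid transform.

    Raises ``ValueError`` if tiles end up closer than the input minimum
    inter-tile distance minus ``overlap_tolerance`` (Angstrom).
    """
    t_axis = np.asarray(target_axis, dtype=float)
    t_axis = t_axis / np.linalg.norm(t_axis)
    if not assembly.tiles:
        raise ValueError("assembly defines no tiles")

    centers_list, normals = _consistent_normals(system, assembly)
    centers = np.asarray(centers_list)

    trimers = assembly.tiles_of_kind("trimer")
    if trimers:
        ref_idx = next(
            i for i, t in enumerate(assembly.tiles) if t.tile_id == trimers[0].tile_id
        )
    else:
        ac = centers.mean(axis=0)
        ref_idx = int(np.argmin(np.linalg.norm(centers - ac, axis=1)))
    c0 = centers[ref_idx]
    n0 = normals[ref_idx]

    # lateral-placement fit uses hexamer centers (stacked trimers would
    # fake curvature in an otherwise flat facet)
    hex_ids = {t.tile_id for t in assembly.tiles_of_kind("hexamer")}
    fit_sel = [i for i, t in enumerate(assembly.tiles) if t.tile_id in hex_ids]
    if len(fit_sel) < 4:
        fit_sel = list(range(len(assembly.tiles)))
    fit_pts = centers[fit_sel]

    # planarity of the fitted centers decides projection vs. pass-through
    fc = fit_pts - fit_pts.mean(axis=0)
    if len(fit_pts) >= 3:
        _, sv, _ = np.linalg.svd(fc, full_matrices=False)
        extent = max(sv[0], 1.0)
        planar = sv[-1] < 1e-6 * extent
    else:
        planar = True

    R0 = align_to_axis(n0, t_axis).rotation
    e1 = _perp_unit(n0)
    e2 = np.cross(n0, e1)
    E1, E2 = R0 @ e1, R0 @ e2

    if planar:
        rel = centers - c0
        xy = np.stack([rel @ e1, rel @ e2], axis=1)
        z = rel @ n0
        scale = 1.0
    else:
        S, radius = _fit_sphere(fit_pts)
        if not np.isfinite(radius) or radius > 1e7:
            raise ValueError("cannot fit a sphere to the tile centers")
        if np.dot(c0 - S, n0) < 0:
            S = c0 + (c0 - S)  # sphere fit landed on the convex side; mirror
        u0 = c0 - S
        d0 = np.linalg.norm(u0)
        nref = u0 / d0
        u = centers - S
        proj = u @ nref
        if np.any(proj <= 0):
            raise ValueError("facet spans more than a hemisphere; cannot project")
        xy = d0 * np.stack([(u @ e1) / proj, (u @ e2) / proj], axis=1)
        z = np.linalg.norm(u, axis=1) - d0
        nn_in = _nn_spacing(centers)
        nn_proj = _nn_spacing(np.column_stack([xy, np.zeros(len(xy))]))
        scale = nn_in / nn_proj if nn_proj > 0 else 1.0

    new_positions = system.positions.copy()
    masks = [assembly.tile_mask(system, t.tile_id) for t in assembly.tiles]
    for i, tile in enumerate(assembly.tiles):
        Ri = align_to_axis(normals[i], t_axis).rotation
        c_new = scale * (xy[i, 0] * E1 + xy[i, 1] * E2) + z[i] * t_axis
        m = masks[i]
        new_positions[m] = (system.positions[m] - centers[i]) @ Ri.T + c_new

    covered = np.zeros(system.n_atoms, dtype=bool)
    for m in masks:
        covered |= m
    if not covered.all():
        # untiled atoms (solvent, ions) are dropped: they have no rigid frame
        keep = covered
        out = system.subset(keep)
        out.positions = new_positions[keep]
    else:
        out = system.with_positions(new_positions)

    if len(masks) > 1:
        d_in = _min_intertile_distance(system.positions, masks)
        sub_masks = [m[covered] for m in masks] if not covered.all() else masks
        d_out = _min_intertile_distance(out.positions, sub_masks)
        if d_out < d_in - overlap_tolerance:
            raise ValueError(
                f"tiles overlap after flattening (min inter-tile distance "
                f"{d_out:.2f} A vs {d_in:.2f} A before); increase tile spacing"
            )
    return out


def _perp_unit(n: np.ndarray) -> np.ndarray:
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        p = e - np.dot(e, n) * n
        if np.linalg.norm(p) > 1e-6:
            return p / np.linalg.norm(p)
    raise ValueError("degenerate normal")


# ---------------------------------------------------------------------------
# periodic cell


def build_periodic_unit(
    flat_system: MolecularSystem,
    assembly: TileAssembly,
    padding: float,
) -> MolecularSystem:
    """Wrap a flattened motif in an orthorhombic periodic box.

    The in-plane cell follows the hexagonal tiling of shell sheets: the
    nearest-neighbor tile spacing ``a`` sets lattice constants ``a``
    along x and ``a*sqrt(3)`` along y, multiplied up to cover the motif
    extent; no in-plane padding is added. The z length is the atomic slab
    thickness plus ``padding`` on each face. Stacked trimer tiles count
    as a single lattice site.
    """
    centers = []
    seen_xy: list[np.ndarray] = []
    for tile in assembly.tiles:
        n = tile_normal_of(flat_system, assembly, tile.tile_id)
        if abs(abs(n[2]) - 1.0) > 1e-4:
            raise ValueError(
                f"tile {tile.tile_id!r} normal {n} is not aligned with z; "
                "flatten the facet first"
            )
        c = tile_center(flat_system, assembly, tile.tile_id)[:2]
        if any(np.linalg.norm(c - s) < 1.0 for s in seen_xy):
            continue  # stacked tile sharing a lattice site
        seen_xy.append(c)
        centers.append(c)
    if len(centers) < 2:
        raise ValueError("need at least 2 distinct tile sites to infer a lattice")
    centers = np.asarray(centers)
    d = cdist(centers, centers)
    np.fill_diagonal(d, np.inf)
    a = float(d.min(axis=1).mean())

    width = centers.max(axis=0) - centers.min(axis=0)
    ax, ay = a, a * math.sqrt(3.0)
    nx = max(1, int(math.floor(width[0] / ax + 0.5)))
    ny = max(1, int(math.floor(width[1] / ay + 0.5)))
    lx, ly = nx * ax, ny * ay

    zmin, zmax = flat_system.positions[:, 2].min(), flat_system.positions[:, 2].max()
    lz = (zmax - zmin) + 2.0 * padding

    box = np.array([lx, ly, lz])
    shift = box / 2.0 - np.array(
        [
            (centers.min(axis=0)[0] + centers.max(axis=0)[0]) / 2.0,
            (centers.min(axis=0)[1] + centers.max(axis=0)[1]) / 2.0,
            (zmin + zmax) / 2.0,
        ]
    )
    return flat_system.with_positions(flat_system.positions + shift, box=box)


# ---------------------------------------------------------------------------
# synthetic density


@dataclass
class DensityGrid:
    """Isotropically sampled density on a regular grid."""

    origin: np.ndarray  # (3,), A, position of voxel (0,0,0)
    spacing: float  # A per voxel
    values: np.ndarray  # (nx, ny, nz), non-negative
    resolution: float  # A (FWHM of the generating Gaussian)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("density values must be finite and non-negative")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def integral(self) -> float:
        """Volume integral of the density (A^3 units)."""
        return float(self.values.sum() * self.spacing**3)

    def peak_position(self) -> np.ndarray:
        """Coordinates of the maximum-density voxel center."""
        idx = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return self.origin + np.array(idx) * self.spacing

    def write_ccp4(self, path: str | Path) -> None:
        """Write as a CCP4/MRC map (via gemmi) for visualization tools."""
        import gemmi

        nx, ny, nz = self.values.shape
        grid = gemmi.FloatGrid(nx, ny, nz)
        grid.set_unit_cell(
            gemmi.UnitCell(
                nx * self.spacing, ny * self.spacing, nz * self.spacing, 90, 90, 90
            )
        )
        grid.spacegroup = gemmi.SpaceGroup("P1")
        arr = np.array(grid, copy=False)
        arr[...] = self.values.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        for w, val in zip((50, 51, 52), self.origin):
            m.set_header_float(w, float(val))
        m.write_ccp4_map(str(path))

    def write_text(self, path: str | Path) -> None:
        """Plain-text debug dump: header lines then one voxel per row."""
        with open(path, "w") as fh:
            fh.write(f"# origin {self.origin[0]} {self.origin[1]} {self.origin[2]}\n")
            fh.write(f"# spacing {self.spacing}\n")
            fh.write(f"# shape {self.values.shape[0]} {self.values.shape[1]} "
                     f"{self.values.shape[2]}\n")
            fh.write(f"# resolution {self.resolution}\n")
            for (i, j, k), v in np.ndenumerate(self.values):
                if v > 0:
                    fh.write(f"{i} {j} {k} {v:.6e}\n")


def synthetic_density(
    system: MolecularSystem, resolution: float, spacing: float
) -> DensityGrid:
    """Gaussian synthetic density map of a system.

    Each atom contributes a unit-peak isotropic Gaussian with
    sigma = resolution / (2 * sqrt(2 ln 2)) — i.e. ``resolution`` is the
    FWHM, the common cryo-EM convention. The grid covers all atoms with a
    2x-resolution margin.
    """
    if system.n_atoms == 0:
        raise ValueError("cannot build a density map for an empty system")
    if resolution <= 0 or spacing <= 0:
        raise ValueError("resolution and spacing must be > 0")
    sigma = resolution / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    margin = 2.0 * resolution
    lo = system.positions.min(axis=0) - margin
    hi = system.positions.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros(shape, dtype=float)
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    cut = 5.0 * sigma
    for pos in system.positions:
        sl = []
        gs = []
        for k in range(3):
            i0 = max(0, int(math.floor((pos[k] - cut - lo[k]) / spacing)))
            i1 = min(shape[k] - 1, int(math.ceil((pos[k] + cut - lo[k]) / spacing)))
            sl.append(slice(i0, i1 + 1))
            x = axes[k][i0 : i1 + 1] - pos[k]
            gs.append(np.exp(-(x**2) / (2.0 * sigma**2)))
        values[sl[0], sl[1], sl[2]] += (
            gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        )
    return DensityGrid(origin=lo, spacing=spacing, values=values, resolution=resolution)
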