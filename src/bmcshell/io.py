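"""Structure and trajectory input/output.

PDB (ATOM/HETATM, CRYST1) and DCD are read and written through
MDAnalysis; this module converts between MDAnalysis universes and the
lightweight columnar containers in :mod:`bmcshell.core`, attaches van der
Waals radii by element, and defines the tile/monomer groupings every
downstream stage consumes.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    Atom,
    MolecularSystem,
    Tile,
    TileAssembly,
    Trajectory,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RADIUS_TABLES",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "assign_tiles",
    "classify_monomers",
    "load_tile_spec",
]

# Van der Waals radii (Angstrom) by element symbol. "simple" is a compact
# Bondi-like set; "hole" matches the default radius file of the classic
# channel-profiling program (larger united-atom carbons).
RADIUS_TABLES: dict[str, dict[str, float]] = {
    "simple": {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80},
    "hole": {"H": 1.00, "C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "P": 2.10},
}

_ELEMENT_SYMBOLS = {
    "H", "C", "N", "O", "S", "P", "F", "K", "I", "B",
    "NA", "CL", "MG", "CA", "ZN", "FE", "MN", "BR", "SE",
}


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in _ELEMENT_SYMBOLS and not stripped[0].isdigit():
        # two-letter symbols only when unambiguous (e.g. CL, NA as ions)
        if two in {"CL", "NA", "MG", "ZN", "FE", "MN", "BR", "SE"} and len(stripped) <= 2:
            return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _universe_to_system(u, radius_table: str, default_radius: float) -> MolecularSystem:
    try:
        table = RADIUS_TABLES[radius_table]
    except KeyError:
        raise ValueError(
            f"unknown radius table {radius_table!r}; known: {sorted(RADIUS_TABLES)}"
        ) from None

    ag = u.atoms
    n = len(ag)
    names = ag.names if hasattr(ag, "names") else np.array(["X"] * n)
    if hasattr(ag, "elements") and all(str(e).strip() for e in ag.elements):
        elements = [str(e).strip().capitalize() for e in ag.elements]
    else:
        elements = [_element_from_name(str(nm)) for nm in names]
    if hasattr(ag, "chainIDs") and all(str(c).strip() for c in ag.chainIDs):
        chains = [str(c) for c in ag.chainIDs]
    else:
        chains = [str(s) for s in ag.segids]

    atoms = []
    warned: set[str] = set()
    for i in range(n):
        el = elements[i]
        key = el.upper() if len(el) > 1 else el
        radius = table.get(key, table.get(key.capitalize()))
        if radius is None:
            radius = table.get(el[0].upper())
        if radius is None:
            if el not in warned:
                logger.warning(
                    "element %r not in radius table %r; using default %.2f A",
                    el, radius_table, default_radius,
                )
                warned.add(el)
            radius = default_radius
        atoms.append(
            Atom(
                index=i,
                name=str(names[i]),
                element=el,
                residue_id=int(ag.resids[i]),
                residue_name=str(ag.resnames[i]),
                chain_id=chains[i],
                position=ag.positions[i].astype(float),
                vdw_radius=float(radius),
            )
        )

    box = None
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(
                "only orthorhombic boxes are supported; got angles "
                f"{tuple(dims[3:])}"
            )
        box = np.asarray(dims[:3], dtype=float)
    return MolecularSystem(atoms, box=box)


def read_structure(
    path: str | Path,
    radius_table: str = "simple",
    default_radius: float = 1.70,
) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    One atom per ATOM/HETATM record; van der Waals radii assigned per
    element from the named table (unknown elements get ``default_radius``
    with a logged warning); the periodic box is taken from CRYST1 when
    present.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _universe_to_system(u, radius_table, default_radius)


def _system_to_universe(system: MolecularSystem, positions: np.ndarray | None = None):
    import MDAnalysis as mda

    n = system.n_atoms
    resid_keys: list[tuple[str, int]] = []
    atom_resindex = np.empty(n, dtype=int)
    for i in range(n):
        key = (system.chain_ids[i], int(system.residue_ids[i]))
        if not resid_keys or resid_keys[-1] != key:
            resid_keys.append(key)
        atom_resindex[i] = len(resid_keys) - 1
    n_res = len(resid_keys)
    seg_keys: list[str] = []
    res_segindex = np.empty(n_res, dtype=int)
    for j, (ch, _) in enumerate(resid_keys):
        if not seg_keys or seg_keys[-1] != ch:
            seg_keys.append(ch)
        res_segindex[j] = len(seg_keys) - 1

    u = mda.Universe.empty(
        n,
        n_residues=n_res,
        n_segments=len(seg_keys),
        atom_resindex=atom_resindex,
        residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(system.names))
    u.add_TopologyAttr("elements", list(system.elements))
    u.add_TopologyAttr("resids", [rid for _, rid in resid_keys])
    first_atom_of_res = np.searchsorted(atom_resindex, np.arange(n_res))
    u.add_TopologyAttr(
        "resnames", [system.residue_names[i] for i in first_atom_of_res]
    )
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", list(system.chain_ids))
    u.atoms.positions = system.positions if positions is None else positions
    if system.box is not None:
        u.dimensions = np.array([*system.box, 90.0, 90.0, 90.0])
    return u


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write a system as a PDB file (CRYST1 included when a box is set)."""
    u = _system_to_universe(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(
    path: str | Path,
    topology: MolecularSystem,
    dt: float,
) -> Trajectory:
    """Read a DCD or multi-model PDB trajectory against a known topology.

    ``dt`` is the time between stored frames in ns; file-internal time
    metadata is ignored.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".dcd":
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            try:
                u.load_new(str(path))
            except Exception as exc:
                raise ValueError(
                    f"cannot read trajectory {path}: atom count may not match "
                    f"topology ({topology.n_atoms} atoms expected): {exc}"
                ) from exc
        else:
            try:
                u = mda.Universe(str(path))
            except Exception as exc:
                raise ValueError(f"cannot read trajectory {path}: {exc}") from exc
    n_file = len(u.atoms)
    if n_file != topology.n_atoms:
        raise ValueError(
            f"trajectory has {n_file} atoms but topology has "
            f"{topology.n_atoms}"
        )
    frames = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)
    if frames.shape[0] == 0:
        raise ValueError(f"trajectory {path} contains no frames")
    return Trajectory(topology=topology, frames=frames, dt=dt)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as DCD or multi-model PDB, by file extension."""
    import MDAnalysis as mda

    path = Path(path)
    u = _system_to_universe(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                w.write(u.atoms)


def assign_tiles(
    system: MolecularSystem,
    spec: Mapping[str, tuple[str, Sequence[str]]],
) -> TileAssembly:
    """Group chains into shell tiles.

    ``spec`` maps tile_id -> (kind, chain_ids) with kind one of
    "hexamer", "trimer_upper", "trimer_lower". Every listed chain must
    exist in the system and appear in exactly one tile.
    """
    present = set(system.chain_ids)
    tiles = []
    for tile_id, (kind, chains) in spec.items():
        missing = [c for c in chains if c not in present]
        if missing:
            raise ValueError(
                f"tile {tile_id!r} lists chains absent from the system: {missing}"
            )
        tiles.append(Tile(tile_id=tile_id, kind=kind, chain_ids=tuple(chains)))
    return TileAssembly(tiles=tiles)


def classify_monomers(
    system: MolecularSystem,
    assembly: TileAssembly,
    contact_cutoff: float = 5.0,
) -> TileAssembly:
    """Label each hexamer chain "buried" or "exposed" by trimer contact.

    A chain is "buried" iff any of its atoms lies within ``contact_cutoff``
    (Angstrom) of any trimer-tile atom; otherwise "exposed". With no trimer
    present every hexamer chain is labeled "exposed" and a warning logged.
    The input assembly is not modified; an updated copy is returned.
    """
    from scipy.spatial import cKDTree

    trimer_mask = np.zeros(system.n_atoms, dtype=bool)
    for tile in assembly.tiles_of_kind("trimer"):
        trimer_mask |= assembly.tile_mask(system, tile.tile_id)

    classes: dict[str, str] = {}
    hexamer_chains = sorted(assembly.hexamer_chains())
    if not trimer_mask.any():
        logger.warning("no trimer tile present; labeling all hexamer chains exposed")
        classes = {c: "exposed" for c in hexamer_chains}
    else:
        tree = cKDTree(system.positions[trimer_mask])
        for chain in hexamer_chains:
            pts = system.positions[system.chain_mask(chain)]
            dmin = tree.query(pts, k=1)[0].min()
            classes[chain] = "buried" if dmin <= contact_cutoff else "exposed"
    return TileAssembly(
        tiles=list(assembly.tiles),
        monomer_class=classes,
        water_selection=assembly.water_selection,
    )


def load_tile_spec(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a plain-text tile specification.

    One tile per line: ``tile_id  kind  chain,chain,...``; blank lines and
    ``#`` comments ignored.
    """
    spec: dict[str, tuple[str, list[str]]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 'tile_id kind chains', got {raw!r}"
            )
        tile_id, kind, chains = parts
        if tile_id in spec:
            raise ValueError(f"{path}:{lineno}: duplicate tile id {tile_id!r}")
        spec[tile_id] = (kind, chains.split(","))
    return spec
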