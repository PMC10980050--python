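"""Core in-memory containers shared by every analysis stage.

Coordinates are in Angstrom throughout; frame times in nanoseconds.
Atom indexing is 0-based internally and only becomes 1-based when a PDB
file is serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularSystem",
    "Trajectory",
    "Tile",
    "TileAssembly",
    "RigidTransform",
    "DEFAULT_SOLVENT_NAMES",
    "DEFAULT_ION_NAMES",
]

#: Residue names treated as solvent (water) by default. TIP3 is the CHARMM
#: water model used in the trajectories this package was written to consume.
DEFAULT_SOLVENT_NAMES = frozenset({"HOH", "TIP3", "WAT", "SOL", "TIP3P"})

#: Residue names treated as monatomic ions by default.
DEFAULT_ION_NAMES = frozenset(
    {"NA", "CL", "SOD", "CLA", "K", "POT", "MG", "CAL", "CA2", "ZN"}
)

TileKind = Literal["hexamer", "trimer_upper", "trimer_lower"]
MonomerClass = Literal["exposed", "buried"]

TILE_CHAIN_COUNT = {"hexamer": 6, "trimer_upper": 3, "trimer_lower": 3}


@dataclass(frozen=True)
class Atom:
    """One atom record: identity, labels and a van der Waals radius."""

    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float  # Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")


class MolecularSystem:
    """A set of atoms with optional orthorhombic periodic box.

    Internally stores columnar numpy arrays for speed; the ``atoms``
    property reconstructs :class:`Atom` records on demand.
    """

    def __init__(self, atoms: Sequence[Atom], box: np.ndarray | None = None):
        atoms = list(atoms)
        indices = [a.index for a in atoms]
        if indices != list(range(len(atoms))):
            raise ValueError("atom indices must be unique and contiguous from 0")
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.positions = (
            np.array([a.position for a in atoms], dtype=float).reshape(-1, 3)
        )
        self.vdw_radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        if box is not None:
            box = np.asarray(box, dtype=float).reshape(3)
            if not np.all(box > 0):
                raise ValueError("box lengths must all be > 0")
        self.box = box

    # -- container protocol ------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        return Atom(
            index=i,
            name=self.names[i],
            element=self.elements[i],
            residue_id=int(self.residue_ids[i]),
            residue_name=self.residue_names[i],
            chain_id=self.chain_ids[i],
            position=self.positions[i].copy(),
            vdw_radius=float(self.vdw_radii[i]),
        )

    @property
    def atoms(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(self.n_atoms))

    # -- selections --------------------------------------------------------
    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def solvent_mask(
        self, solvent_names: Iterable[str] = DEFAULT_SOLVENT_NAMES
    ) -> np.ndarray:
        return np.isin(self.residue_names, list(solvent_names))

    def ion_mask(self, ion_names: Iterable[str] = DEFAULT_ION_NAMES) -> np.ndarray:
        return np.isin(self.residue_names, list(ion_names))

    def protein_mask(self) -> np.ndarray:
        return ~(self.solvent_mask() | self.ion_mask())

    def subset(self, mask: np.ndarray) -> "MolecularSystem":
        """New system containing the masked atoms, reindexed from 0."""
        idx = np.flatnonzero(mask)
        atoms = [
            Atom(
                index=j,
                name=self.names[i],
                element=self.elements[i],
                residue_id=int(self.residue_ids[i]),
                residue_name=self.residue_names[i],
                chain_id=self.chain_ids[i],
                position=self.positions[i].copy(),
                vdw_radius=float(self.vdw_radii[i]),
            )
            for j, i in enumerate(idx)
        ]
        return MolecularSystem(atoms, box=None if self.box is None else self.box.copy())

    def with_positions(self, positions: np.ndarray, box=None) -> "MolecularSystem":
        """Shallow copy sharing labels but with replaced coordinates."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != self.positions.shape:
            raise ValueError("replacement coordinates have wrong shape")
        out = MolecularSystem.__new__(MolecularSystem)
        out.names = self.names
        out.elements = self.elements
        out.residue_ids = self.residue_ids
        out.residue_names = self.residue_names
        out.chain_ids = self.chain_ids
        out.vdw_radii = self.vdw_radii
        out.positions = positions.copy()
        if box is not None:
            box = np.asarray(box, dtype=float).reshape(3)
        elif self.box is not None:
            box = self.box.copy()
        out.box = box
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``dt`` is the time between *stored* frames in nanoseconds.
    """

    topology: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3) Angstrom
    dt: float  # ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time of each stored frame in ns (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.dt

    def frame_system(self, i: int) -> MolecularSystem:
        return self.topology.with_positions(self.frames[i])


@dataclass(frozen=True)
class Tile:
    tile_id: str
    kind: TileKind
    chain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = TILE_CHAIN_COUNT[self.kind]
        if len(self.chain_ids) != expected:
            raise ValueError(
                f"tile {self.tile_id!r} of kind {self.kind} must have "
                f"{expected} chains, got {len(self.chain_ids)}"
            )
        if len(set(self.chain_ids)) != len(self.chain_ids):
            raise ValueError(f"tile {self.tile_id!r} lists a chain twice")


@dataclass
class TileAssembly:
    """Grouping of chains into shell tiles plus monomer classes.

    ``monomer_class`` maps each hexamer chain to "exposed" (solvent-facing
    edge) or "buried" (interfacing the central trimer); it is filled by
    :func:`bmcshell.io.classify_monomers`.
    """

    tiles: list[Tile]
    monomer_class: dict[str, MonomerClass] = field(default_factory=dict)
    water_selection: Callable[[str], bool] = field(
        default=lambda resname: resname in DEFAULT_SOLVENT_NAMES
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for tile in self.tiles:
            for ch in tile.chain_ids:
                if ch in seen:
                    raise ValueError(
                        f"chain {ch!r} appears in tiles {seen[ch]!r} and "
                        f"{tile.tile_id!r}; every chain belongs to exactly one tile"
                    )
                seen[ch] = tile.tile_id

    def tiles_of_kind(self, kind: str) -> list[Tile]:
        if kind == "trimer":
            return [t for t in self.tiles if t.kind.startswith("trimer")]
        return [t for t in self.tiles if t.kind == kind]

    def tile(self, tile_id: str) -> Tile:
        for t in self.tiles:
            if t.tile_id == tile_id:
                return t
        raise KeyError(tile_id)

    def tile_mask(self, system: MolecularSystem, tile_id: str) -> np.ndarray:
        t = self.tile(tile_id)
        return np.isin(system.chain_ids, list(t.chain_ids))

    def hexamer_chains(self) -> list[str]:
        out: list[str] = []
        for t in self.tiles_of_kind("hexamer"):
            out.extend(t.chain_ids)
        return out

    def chains_in_class(self, class_filter: str) -> list[str]:
        """Hexamer chains passing an {exposed, buried, all} filter."""
        chains = self.hexamer_chains()
        if class_filter == "all":
            return chains
        if class_filter not in ("exposed", "buried"):
            raise ValueError(f"unknown class filter {class_filter!r}")
        return [c for c in chains if self.monomer_class.get(c) == class_filter]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)
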