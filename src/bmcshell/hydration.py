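"""Water-protein association statistics.

Two bespoke per-residue measures used to compare shell and sheet
morphologies:

* contact counts — the number of distinct water molecules with any atom
  within a cutoff (default 5 A) of any atom of a residue, averaged over
  frames and over the hexamer monomers of a chosen class;
* dual-cutoff residence times — a clock that starts when a water first
  comes within the enter cutoff (5 A) of a residue and stops only when
  it moves beyond the exit cutoff (8 A). The 3 A hysteresis band keeps
  boundary flicker from fragmenting one visit into many short events.

All distances are atom-to-atom minima under the minimum-image convention
when the system has an orthorhombic box.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import MolecularSystem, TileAssembly, Trajectory

__all__ = [
    "ResidenceEvent",
    "water_contacts",
    "residence_events",
    "mean_residence",
    "mean_contacts",
]


class ResidenceEvent(NamedTuple):
    water_id: tuple[str, int]  # (chain_id, residue_id) of the water
    start_frame: int
    duration_frames: int
    censored: bool


# ---------------------------------------------------------------------------
# selection helpers


def _residue_mask(
    system: MolecularSystem, residue: tuple[str, int]
) -> np.ndarray:
    chain, resid = residue
    mask = (system.chain_ids == chain) & (system.residue_ids == resid)
    if not mask.any():
        raise ValueError(f"residue {residue!r} has no atoms")
    return mask


def _water_mask(system: MolecularSystem, assembly: TileAssembly | None) -> np.ndarray:
    if assembly is None:
        return system.solvent_mask()
    sel = np.array(
        [assembly.water_selection(rn) for rn in system.residue_names], dtype=bool
    )
    return sel


def _water_groups(system: MolecularSystem, water_mask: np.ndarray):
    """(atom indices, group index per atom, group labels) for water residues."""
    idx = np.flatnonzero(water_mask)
    labels = [
        (system.chain_ids[i], int(system.residue_ids[i])) for i in idx
    ]
    uniq: dict[tuple[str, int], int] = {}
    group = np.empty(len(idx), dtype=int)
    for k, lab in enumerate(labels):
        group[k] = uniq.setdefault(lab, len(uniq))
    return idx, group, list(uniq)


def _min_image_dists(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """(len(a), len(b)) distance matrix under minimum image."""
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=2))


# ---------------------------------------------------------------------------
# contacts


def water_contacts(
    frame: np.ndarray,
    system: MolecularSystem,
    residue: tuple[str, int],
    cutoff: float = 5.0,
    water_mask: np.ndarray | None = None,
) -> int:
    """Number of distinct waters within ``cutoff`` of a residue in a frame.

    A water counts once no matter how many of its atoms are within the
    cutoff of however many residue atoms. ``frame`` is an (n_atoms, 3)
    coordinate array sharing the system's topology.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    rmask = _residue_mask(system, residue)
    if water_mask is None:
        water_mask = system.solvent_mask()
    widx, wgroup, _ = _water_groups(system, water_mask)
    if len(widx) == 0:
        return 0
    d = _min_image_dists(frame[widx], frame[rmask], system.box)
    hit = (d <= cutoff).any(axis=1)
    return int(len(np.unique(wgroup[hit])))


# ---------------------------------------------------------------------------
# residence clock


def _per_frame_water_distances(
    traj: Trajectory,
    rmask: np.ndarray,
    widx: np.ndarray,
    wgroup: np.ndarray,
    n_groups: int,
) -> np.ndarray:
    """(n_frames, n_waters) minimum residue-water distance per frame."""
    box = traj.topology.box
    out = np.empty((traj.n_frames, n_groups))
    for fi in range(traj.n_frames):
        frame = traj.frames[fi]
        d = _min_image_dists(frame[widx], frame[rmask], box).min(axis=1)
        out[fi] = np.full(n_groups, np.inf)
        np.minimum.at(out[fi], wgroup, d)
    return out


def residence_events(
    traj: Trajectory,
    residue: tuple[str, int],
    enter_cutoff: float = 5.0,
    exit_cutoff: float = 8.0,
    water_mask: np.ndarray | None = None,
) -> list[ResidenceEvent]:
    """Dual-cutoff residence events of every water around one residue.

    An event opens at the first frame a water's minimum distance to the
    residue is <= ``enter_cutoff`` (with no event already open for that
    water); it stays open while the distance remains <= ``exit_cutoff``
    and closes at the first frame the distance exceeds it, with
    ``duration = close_frame - start_frame``. A water re-entering after
    closing starts a new event. Events still open at the final frame are
    flagged censored with duration measured to the last frame.
    """
    if enter_cutoff >= exit_cutoff:
        raise ValueError(
            f"enter_cutoff ({enter_cutoff}) must be < exit_cutoff ({exit_cutoff})"
        )
    system = traj.topology
    rmask = _residue_mask(system, residue)
    if water_mask is None:
        water_mask = system.solvent_mask()
    widx, wgroup, wlabels = _water_groups(system, water_mask)
    if len(widx) == 0:
        return []
    dists = _per_frame_water_distances(traj, rmask, widx, wgroup, len(wlabels))

    events: list[ResidenceEvent] = []
    n_frames = traj.n_frames
    for w, label in enumerate(wlabels):
        open_start: int | None = None
        for fi in range(n_frames):
            d = dists[fi, w]
            if open_start is None:
                if d <= enter_cutoff:
                    open_start = fi
            elif d > exit_cutoff:
                events.append(
                    ResidenceEvent(label, open_start, fi - open_start, False)
                )
                open_start = fi if d <= enter_cutoff else None
        if open_start is not None:
            events.append(
                ResidenceEvent(label, open_start, (n_frames - 1) - open_start, True)
            )
    events.sort(key=lambda e: (e.start_frame, e.water_id))
    return events


# ---------------------------------------------------------------------------
# per-residue tables pooled over monomers


def _chain_protein_residues(
    system: MolecularSystem, chain: str
) -> list[tuple[int, str]]:
    mask = system.chain_mask(chain) & system.protein_mask()
    out: list[tuple[int, str]] = []
    seen: set[int] = set()
    for i in np.flatnonzero(mask):
        rid = int(system.residue_ids[i])
        if rid not in seen:
            seen.add(rid)
            out.append((rid, system.residue_names[i]))
    return out


def _selected_chains(assembly: TileAssembly, class_filter: str) -> list[str]:
    chains = assembly.chains_in_class(class_filter)
    if not chains:
        raise ValueError(f"no hexamer monomer passes class filter {class_filter!r}")
    return chains


def mean_residence(
    traj: Trajectory,
    assembly: TileAssembly,
    class_filter: str = "all",
    enter_cutoff: float = 5.0,
    exit_cutoff: float = 8.0,
    include_censored: bool = True,
) -> pd.DataFrame:
    """Mean water residence time per residue position, pooled over monomers.

    Residue positions are aligned across monomers by residue number (the
    monomers of a tile kind share one sequence). Event durations are
    converted to ns with the trajectory's frame spacing; censored
    (trajectory-end) events enter at their observed length unless
    ``include_censored`` is False. Returns a DataFrame with columns
    (residue_id, residue_name, mean_residence_ns, event_count,
    censored_count, class); ``n_monomers_averaged`` is in ``.attrs``.
    """
    system = traj.topology
    chains = _selected_chains(assembly, class_filter)
    wmask = _water_mask(system, assembly)
    pooled: dict[tuple[int, str], list[ResidenceEvent]] = {}
    for chain in chains:
        for rid, rname in _chain_protein_residues(system, chain):
            evs = residence_events(
                traj, (chain, rid), enter_cutoff, exit_cutoff, water_mask=wmask
            )
            pooled.setdefault((rid, rname), []).extend(evs)
    rows = []
    for (rid, rname), evs in sorted(pooled.items()):
        used = evs if include_censored else [e for e in evs if not e.censored]
        durations = np.array([e.duration_frames for e in used], dtype=float)
        rows.append(
            {
                "residue_id": rid,
                "residue_name": rname,
                "mean_residence_ns": (
                    float(durations.mean() * traj.dt) if len(durations) else 0.0
                ),
                "event_count": len(evs),
                "censored_count": sum(e.censored for e in evs),
                "class": class_filter,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_monomers_averaged"] = len(chains)
    df.attrs["dt_ns"] = traj.dt
    return df


def mean_contacts(
    traj: Trajectory,
    assembly: TileAssembly,
    class_filter: str = "all",
    cutoff: float = 5.0,
    stride: int = 1,
) -> pd.DataFrame:
    """Mean unique-water contacts per residue, pooled over monomers.

    Averages :func:`water_contacts` over every ``stride``-th frame and
    over all hexamer monomers passing ``class_filter``. Returns a
    DataFrame with columns (residue_id, residue_name, mean_contacts,
    n_frames, class); ``n_monomers_averaged`` is in ``.attrs``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    system = traj.topology
    chains = _selected_chains(assembly, class_filter)
    wmask = _water_mask(system, assembly)
    frame_ids = list(range(0, traj.n_frames, stride))
    counts: dict[tuple[int, str], list[int]] = {}
    for fi in frame_ids:
        frame = traj.frames[fi]
        for chain in chains:
            for rid, rname in _chain_protein_residues(system, chain):
                c = water_contacts(frame, system, (chain, rid), cutoff, wmask)
                counts.setdefault((rid, rname), []).append(c)
    rows = [
        {
            "residue_id": rid,
            "residue_name": rname,
            "mean_contacts": float(np.mean(vals)),
            "n_frames": len(frame_ids),
            "class": class_filter,
        }
        for (rid, rname), vals in sorted(counts.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_monomers_averaged"] = len(chains)
    return df
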