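"""Water contact counts and the dual-cutoff residence clock."""

import numpy as np
import pytest

from bmcshell.core import Atom, MolecularSystem, Tile, TileAssembly, Trajectory
from bmcshell.hydration import (
    mean_contacts,
    mean_residence,
    residence_events,
    water_contacts,
)
from bmcshell.synthetic import make_hydration_trajectory
from conftest import brute_force_water_contacts, make_water_bath


def _protein_atom(idx, chain, resid, pos):
    return Atom(idx, "CA", "C", resid, "GLY", chain, np.asarray(pos, float), 1.7)


def _water(idx, resid, pos, chain="W"):
    return Atom(idx, "OH2", "O", resid, "TIP3", chain, np.asarray(pos, float), 1.52)


def _trace_trajectory(distances, extra_waters=()):
    """One protein atom at origin; water 1's distance follows ``distances``."""
    atoms = [_protein_atom(0, "A", 1, [0, 0, 0]), _water(1, 1, [50, 0, 0])]
    for k, _ in enumerate(extra_waters):
        atoms.append(_water(2 + k, 2 + k, [60.0 + k, 0, 0]))
    topo = MolecularSystem(atoms)
    frames = np.tile(topo.positions, (len(distances), 1, 1))
    for fi, d in enumerate(distances):
        frames[fi, 1] = [d, 0.0, 0.0]
        for k, trace in enumerate(extra_waters):
            frames[fi, 2 + k] = [trace[fi], 0.0, 0.0]
    return Trajectory(topology=topo, frames=frames, dt=1.0)


class TestWaterContacts:
    def test_cutoff_boundary(self):
        topo = MolecularSystem(
            [_protein_atom(0, "A", 1, [0, 0, 0]), _water(1, 1, [4.9, 0, 0])]
        )
        assert water_contacts(topo.positions, topo, ("A", 1)) == 1
        topo2 = MolecularSystem(
            [_protein_atom(0, "A", 1, [0, 0, 0]), _water(1, 1, [5.1, 0, 0])]
        )
        assert water_contacts(topo2.positions, topo2, ("A", 1)) == 0

    def test_multi_atom_water_counts_once(self):
        atoms = [_protein_atom(0, "A", 1, [0, 0, 0])]
        for j, off in enumerate([[3, 0, 0], [3.5, 0.8, 0], [3.5, -0.8, 0]]):
            atoms.append(
                Atom(1 + j, ["OH2", "H1", "H2"][j], "O" if j == 0 else "H",
                     1, "TIP3", "W", np.asarray(off, float), 1.0)
            )
        topo = MolecularSystem(atoms)
        assert water_contacts(topo.positions, topo, ("A", 1)) == 1

    def test_minimum_image_wraps_box(self):
        atoms = [_protein_atom(0, "A", 1, [0.5, 5, 5]), _water(1, 1, [19.5, 5, 5])]
        topo = MolecularSystem(atoms, box=np.array([20.0, 20.0, 20.0]))
        # direct distance 19 A, minimum-image distance 1 A
        assert water_contacts(topo.positions, topo, ("A", 1)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        protein = [
            _protein_atom(0, "A", 1, [10, 10, 10]),
            _protein_atom(1, "A", 1, [12, 10, 10]),
        ]
        sys = make_water_bath(100, box=20.0, seed=seed, protein_atoms=protein)
        ours = water_contacts(sys.positions, sys, ("A", 1))
        oracle = brute_force_water_contacts(
            sys.positions.copy(), sys, ("A", 1), 5.0
        )
        assert ours == oracle

    def test_missing_residue_is_hard_error(self):
        topo = MolecularSystem([_protein_atom(0, "A", 1, [0, 0, 0])])
        with pytest.raises(ValueError, match="no atoms"):
            water_contacts(topo.positions, topo, ("B", 9))


class TestResidenceEvents:
    def test_hysteresis_keeps_band_frames_inside(self):
        traj = _trace_trajectory([3, 4, 6, 7, 9])
        events = residence_events(traj, ("A", 1))
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.duration_frames, ev.censored) == (0, 4, False)

    def test_exit_and_reentry_gives_two_events(self):
        traj = _trace_trajectory([3, 9, 3, 9])
        events = residence_events(traj, ("A", 1))
        assert [(e.start_frame, e.duration_frames) for e in events] == [
            (0, 1), (2, 1),
        ]

    def test_band_only_never_starts_clock(self):
        traj = _trace_trajectory([6, 6, 6])
        assert residence_events(traj, ("A", 1)) == []

    def test_open_event_at_end_is_censored(self):
        traj = _trace_trajectory([9, 3, 3, 3])
        events = residence_events(traj, ("A", 1))
        assert len(events) == 1
        assert events[0].censored
        assert events[0].start_frame == 1
        assert events[0].duration_frames == 2  # to the last frame

    def test_equal_cutoffs_rejected(self):
        traj = _trace_trajectory([3, 9])
        with pytest.raises(ValueError, match="enter_cutoff"):
            residence_events(traj, ("A", 1), enter_cutoff=5, exit_cutoff=5)

    def test_hysteresis_merges_flicker(self):
        """A near-degenerate band fragments boundary flicker into more,
        shorter events than the 5/8 A dual cutoff."""
        flicker = [3, 6, 3, 6, 3, 9]
        traj = _trace_trajectory(flicker)
        dual = residence_events(traj, ("A", 1), 5.0, 8.0)
        tight = residence_events(traj, ("A", 1), 5.0, 5.0 + 1e-9)
        assert len(tight) >= len(dual)
        assert np.mean([e.duration_frames for e in tight]) <= np.mean(
            [e.duration_frames for e in dual]
        )

    def test_invariant_under_water_reindexing(self):
        rng = np.random.default_rng(4)
        traces = rng.uniform(2.0, 12.0, size=(3, 6))
        traj = _trace_trajectory(traces[:, 0], extra_waters=[traces[:, 1]])
        evs = residence_events(traj, ("A", 1))
        # swap the two waters' identities
        atoms = [traj.topology.atom(i) for i in range(3)]
        swapped = MolecularSystem(
            [
                atoms[0],
                Atom(1, "OH2", "O", 2, "TIP3", "W", atoms[2].position, 1.52),
                Atom(2, "OH2", "O", 1, "TIP3", "W", atoms[1].position, 1.52),
            ]
        )
        frames = traj.frames[:, [0, 2, 1], :]
        evs_swapped = residence_events(
            Trajectory(topology=swapped, frames=frames, dt=1.0), ("A", 1)
        )
        key = lambda evts: sorted(
            (e.start_frame, e.duration_frames, e.censored) for e in evts
        )
        assert key(evs) == key(evs_swapped)

    def test_total_event_frames_bounded_by_trajectory(self):
        rng = np.random.default_rng(9)
        n_frames = 40
        walk = np.clip(4 + np.cumsum(rng.normal(0, 2, n_frames)), 0.5, 30)
        traj = _trace_trajectory(walk)
        events = residence_events(traj, ("A", 1))
        total = sum(e.duration_frames for e in events)
        assert total <= n_frames


def _hexamer_assembly():
    return TileAssembly(
        tiles=[Tile("hex", "hexamer", tuple("ABCDEF"))],
        monomer_class={c: "buried" for c in "ABCDEF"},
    )


def _monomer_trajectory(events_by_chain, n_frames=20, dt=0.1):
    """Six 1-atom monomers far apart; scripted water visits per chain."""
    atoms = []
    for ci, ch in enumerate("ABCDEF"):
        atoms.append(_protein_atom(ci, ch, 1, [100.0 * ci, 0, 0]))
    widx = len(atoms)
    schedules = []
    for ch, evs in events_by_chain.items():
        for start, dur in evs:
            schedules.append((widx, ch, start, dur))
            atoms.append(_water(widx, widx, [500.0 + widx * 20, 200, 0]))
            widx += 1
    topo = MolecularSystem(atoms)
    frames = np.tile(topo.positions, (n_frames, 1, 1))
    for ai, ch, start, dur in schedules:
        target = topo.positions[ord(ch) - ord("A")]
        for f in range(start, min(start + dur, n_frames)):
            frames[f, ai] = target + [3.0, 0, 0]
    return Trajectory(topology=topo, frames=frames, dt=dt)


class TestPooledTables:
    def test_single_event_arithmetic(self):
        traj = _monomer_trajectory({"A": [(2, 10)]}, n_frames=20, dt=0.1)
        df = mean_residence(traj, _hexamer_assembly(), class_filter="buried")
        row = df[df.residue_id == 1].iloc[0]
        assert row.mean_residence_ns == pytest.approx(1.0)
        assert row.event_count == 1

    def test_pooling_across_monomers(self):
        traj = _monomer_trajectory(
            {"A": [(1, 2), (6, 4)], "B": [(3, 6)]}, n_frames=20, dt=0.1
        )
        df = mean_residence(traj, _hexamer_assembly(), class_filter="all")
        row = df[df.residue_id == 1].iloc[0]
        assert row.mean_residence_ns == pytest.approx(4 * 0.1)
        assert row.event_count == 3
        assert df.attrs["n_monomers_averaged"] == 6

    def test_censored_inclusion_toggle(self):
        traj = _monomer_trajectory({"A": [(2, 5), (15, 10)]}, n_frames=20, dt=0.1)
        with_c = mean_residence(traj, _hexamer_assembly())
        without_c = mean_residence(traj, _hexamer_assembly(),
                                   include_censored=False)
        r_with = with_c[with_c.residue_id == 1].iloc[0]
        r_without = without_c[without_c.residue_id == 1].iloc[0]
        assert r_with.censored_count == 1
        assert r_without.mean_residence_ns == pytest.approx(0.5)
        assert r_with.mean_residence_ns == pytest.approx((5 + 4) / 2 * 0.1)

    def test_scripted_generator_events_recovered_exactly(self):
        traj, truth = make_hydration_trajectory(
            mean_dwell_ns=10.0, n_waters=15, n_frames=120, seed=5
        )
        rec = residence_events(traj, ("A", 1))
        assert [tuple(e) for e in rec] == [tuple(e) for e in truth]

    def test_exponential_dwell_mean_recovered(self):
        traj, truth = make_hydration_trajectory(
            mean_dwell_ns=30.0, n_waters=30, n_frames=900, dt=1.0, seed=2024
        )
        assert len(truth) >= 200
        rec = residence_events(traj, ("A", 1))
        mean_ns = np.mean([e.duration_frames for e in rec]) * traj.dt
        assert abs(mean_ns / 30.0 - 1.0) < 0.15

    def test_mean_contacts_uniform_value(self):
        traj = _monomer_trajectory({"A": [(0, 20)]}, n_frames=20, dt=0.1)
        df = mean_contacts(traj, _hexamer_assembly(), class_filter="all")
        row = df[df.residue_id == 1].iloc[0]
        # one water near one of six monomers, every frame
        assert row.mean_contacts == pytest.approx(1.0 / 6.0)

    def test_stride_semantics(self):
        # water near chain A only on even frames
        atoms = [_protein_atom(0, "A", 1, [0, 0, 0]), _water(1, 1, [50, 0, 0])]
        for ci, ch in enumerate("BCDEF"):
            atoms.append(_protein_atom(2 + ci, ch, 1, [100.0 * (ci + 1), 0, 0]))
        topo = MolecularSystem(atoms)
        frames = np.tile(topo.positions, (10, 1, 1))
        for f in range(0, 10, 2):
            frames[f, 1] = [3.0, 0, 0]
        traj = Trajectory(topology=topo, frames=frames, dt=1.0)
        asm = _hexamer_assembly()
        df = mean_contacts(traj, asm, stride=2)
        row = df[df.residue_id == 1].iloc[0]
        assert row.n_frames == 5
        assert row.mean_contacts == pytest.approx(1.0 / 6.0)  # all even frames

    def test_surface_exceeds_occluded_in_uniform_bath(self):
        """Solvent-exposed beads accumulate more unique-water contacts than
        a sterically occluded bead in a uniform bath."""
        rng = np.random.default_rng(12)
        atoms = []
        # six chains: resid 1 = surface bead at radius 10, resid 2 = buried
        # bead near the origin
        for ci, ch in enumerate("ABCDEF"):
            a = 2 * np.pi * ci / 6
            atoms.append(
                _protein_atom(len(atoms), ch, 1,
                              [10 * np.cos(a), 10 * np.sin(a), 0.0])
            )
            atoms.append(
                _protein_atom(len(atoms), ch, 2,
                              [0.8 * np.cos(a), 0.8 * np.sin(a), 0.0])
            )
        # occluder shell (untiled chain) blocking water from the center
        for k in range(60):
            v = rng.normal(size=3)
            v *= 3.0 / np.linalg.norm(v)
            atoms.append(Atom(len(atoms), "C", "C", k + 1, "OCC", "X", v, 1.7))
        n0 = len(atoms)
        placed = 0
        while placed < 120:
            p = rng.uniform(-15, 15, size=3)
            if np.linalg.norm(p) < 6.5:
                continue
            atoms.append(_water(n0 + placed, placed + 1, p))
            placed += 1
        topo = MolecularSystem(atoms)
        traj = Trajectory(topology=topo, frames=topo.positions[None], dt=1.0)
        df = mean_contacts(traj, _hexamer_assembly(), class_filter="all")
        surface = df[df.residue_id == 1].iloc[0].mean_contacts
        buried = df[df.residue_id == 2].iloc[0].mean_contacts
        assert surface > buried
        assert buried == 0.0
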