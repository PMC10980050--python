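"""Pore normals, axis alignment, flattening, periodic cells, density maps."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from bmcshell.geometry import (
    align_to_axis,
    build_periodic_unit,
    flatten_facet,
    synthetic_density,
    tile_center,
    tile_normal,
    tile_normal_of,
)
from bmcshell.metrics import superpose
from bmcshell.synthetic import (
    RingSpec,
    make_facet,
    make_ring_channel,
    make_sheet_unit,
)

Z = np.array([0.0, 0.0, 1.0])


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


TRIANGLE = np.array([[1.0, 0, 0], [-0.5, math.sqrt(3) / 2, 0],
                     [-0.5, -math.sqrt(3) / 2, 0]])


class TestTileNormal:
    def test_ccw_triangle_gives_plus_z(self):
        assert np.allclose(tile_normal(TRIANGLE), Z)

    def test_cw_triangle_flipped_outward(self):
        cw = TRIANGLE[::-1]
        below = np.array([0.0, 0.0, -10.0])
        assert np.allclose(tile_normal(cw, assembly_centroid=below), Z)

    def test_rotated_triangle(self):
        R = _rotation([1, 2, 3], 0.7)
        pts = TRIANGLE @ R.T
        n = tile_normal(pts, assembly_centroid=-10 * (R @ Z))
        assert np.abs(n - R @ Z).max() < 1e-8

    def test_collinear_points_error(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            tile_normal(pts)


class TestAlignToAxis:
    def test_identity(self):
        t = align_to_axis(Z, Z)
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, 0)

    def test_x_to_z(self):
        x = np.array([1.0, 0, 0])
        t = align_to_axis(x, Z)
        assert np.abs(t.apply(x) - Z).max() < 1e-8

    def test_random_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            tr = align_to_axis(n, t)
            assert np.linalg.norm(tr.apply(n) - t) < 1e-8
            assert abs(np.linalg.det(tr.rotation) - 1) < 1e-8

    def test_antiparallel_deterministic(self):
        t1 = align_to_axis(Z, -Z)
        t2 = align_to_axis(Z, -Z)
        assert np.allclose(t1.rotation, t2.rotation)
        assert np.abs(t1.apply(Z) + Z).max() < 1e-8

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            align_to_axis(np.array([2.0, 0, 0]), Z)


class TestFlattenFacet:
    def test_planar_input_is_fixed_point(self, flat_facet):
        sys, asm = flat_facet
        out = flatten_facet(sys, asm)
        _, rmsd = superpose(out.positions, sys.positions)
        assert rmsd < 1e-6

    def test_cap_normals_hit_target(self, curved_facet):
        sys, asm = curved_facet
        out = flatten_facet(sys, asm)
        for t in asm.tiles:
            n = tile_normal_of(out, asm, t.tile_id)
            assert np.abs(n - Z).max() < 1e-6

    def test_transforms_are_rigid_per_tile(self, curved_facet):
        sys, asm = curved_facet
        out = flatten_facet(sys, asm)
        for t in asm.tiles:
            m = asm.tile_mask(sys, t.tile_id)
            assert np.abs(
                pdist(sys.positions[m]) - pdist(out.positions[m])
            ).max() < 1e-6

    def test_reference_trimer_lands_at_origin(self):
        sys, asm = make_facet(
            n_tiles=7, curvature_radius=250.0, central_trimer=True,
            stacked_trimer=True,
        )
        out = flatten_facet(sys, asm)
        upper = asm.tiles_of_kind("trimer_upper")[0]
        assert np.linalg.norm(tile_center(out, asm, upper.tile_id)) < 1e-6
        lower = asm.tiles_of_kind("trimer_lower")[0]
        c_lo = tile_center(out, asm, lower.tile_id)
        assert np.linalg.norm(c_lo[:2]) < 0.5  # stacked pair stays coaxial
        assert c_lo[2] < -1.0

    def test_intertile_spacing_preserved_within_5pct(self, curved_facet):
        sys, asm = curved_facet
        out = flatten_facet(sys, asm)
        cin = np.array([tile_center(sys, asm, t.tile_id) for t in asm.tiles])
        cout = np.array([tile_center(out, asm, t.tile_id) for t in asm.tiles])
        din, dout = pdist(cin), pdist(cout)
        assert np.max(np.abs(dout - din) / din) < 0.05

    def test_curvature_to_zero_limit(self):
        prev = np.inf
        for radius in (400.0, 1600.0, 6400.0):
            sys, asm = make_facet(n_tiles=7, curvature_radius=radius)
            out = flatten_facet(sys, asm)
            dev = np.sqrt(((out.positions - sys.positions) ** 2).sum(1).mean())
            assert dev < prev / 2
            prev = dev
        assert prev < 0.1

    def test_no_new_overlaps(self, curved_facet):
        sys, asm = curved_facet
        out = flatten_facet(sys, asm)
        masks = [asm.tile_mask(sys, t.tile_id) for t in asm.tiles]

        def min_intertile(pos):
            best = np.inf
            for i in range(len(masks)):
                for j in range(i + 1, len(masks)):
                    best = min(best, cdist(pos[masks[i]], pos[masks[j]]).min())
            return best

        assert min_intertile(out.positions) >= min_intertile(sys.positions) - 1.0


class TestBuildPeriodicUnit:
    def test_z_is_slab_plus_padding(self):
        sys, asm = make_sheet_unit(spacing=26.0, trimer_gap=8.0)
        out = build_periodic_unit(sys, asm, padding=20.0)
        slab = sys.positions[:, 2].max() - sys.positions[:, 2].min()
        assert out.box[2] == pytest.approx(slab + 40.0)

    def test_hexagonal_lattice_constants(self):
        a = 60.0
        sys, asm = make_facet(n_tiles=2, curvature_radius=np.inf, spacing=a)
        out = build_periodic_unit(sys, asm, padding=10.0)
        assert out.box[0] == pytest.approx(a)
        assert out.box[1] == pytest.approx(a * math.sqrt(3))

    def test_minimum_image_neighbor_spacing(self):
        """Brute-force nearest-image scan: a tile's nearest periodic
        neighbor sits at the intra-cell tile spacing within 2%."""
        a = 26.0
        sys, asm = make_sheet_unit(spacing=a)
        out = build_periodic_unit(sys, asm, padding=15.0)
        centers = np.array(
            [
                tile_center(out, asm, t.tile_id)
                for t in asm.tiles
                if t.kind != "trimer_lower"
            ]
        )
        box = out.box
        best = np.inf
        for i in range(len(centers)):
            for j in range(len(centers)):
                for sx in (-1, 0, 1):
                    for sy in (-1, 0, 1):
                        if i == j and sx == 0 and sy == 0:
                            continue
                        shift = np.array([sx * box[0], sy * box[1], 0.0])
                        d = np.linalg.norm(centers[i] - centers[j] - shift)
                        best = min(best, d)
        assert abs(best - a) / a < 0.02

    def test_trimer_surrounded_by_hexamers_under_images(self):
        a = 26.0
        sys, asm = make_sheet_unit(spacing=a)
        out = build_periodic_unit(sys, asm, padding=15.0)
        box = out.box
        trimer = tile_center(out, asm, asm.tiles_of_kind("trimer_upper")[0].tile_id)
        hexes = [
            tile_center(out, asm, t.tile_id) for t in asm.tiles_of_kind("hexamer")
        ]
        neighbors = []
        for h in hexes:
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    img = h + np.array([sx * box[0], sy * box[1], 0.0])
                    d = np.linalg.norm((img - trimer)[:2])
                    if abs(d - a) < 0.5:
                        neighbors.append(img)
        assert len(neighbors) == 6  # full hexagonal shell of hexamer images

    def test_single_tile_errors(self):
        sys, asm = make_facet(n_tiles=1, curvature_radius=np.inf)
        with pytest.raises(ValueError, match="lattice"):
            build_periodic_unit(sys, asm, padding=10.0)


class TestSyntheticDensity:
    def test_peak_at_single_atom(self):
        sys = make_ring_channel([RingSpec(0.0, 5.0, 1, 1.5)])
        g = synthetic_density(sys, resolution=4.0, spacing=1.0)
        assert np.linalg.norm(g.peak_position() - sys.positions[0]) <= math.sqrt(3) / 2

    def test_additivity_of_far_atoms(self):
        one = make_ring_channel([RingSpec(0.0, 5.0, 1, 1.5)])
        two = make_ring_channel([RingSpec(0.0, 5.0, 1, 1.5),
                                 RingSpec(100.0, 5.0, 1, 1.5)])
        g1 = synthetic_density(one, resolution=4.0, spacing=1.0)
        g2 = synthetic_density(two, resolution=4.0, spacing=1.0)
        assert g2.integral() == pytest.approx(2 * g1.integral(), rel=0.01)

    def test_integral_matches_gaussian_mass(self):
        sys = make_ring_channel([RingSpec(0.0, 5.0, 12, 1.5)])
        g = synthetic_density(sys, resolution=4.0, spacing=1.0)
        sigma = 4.0 / (2 * math.sqrt(2 * math.log(2)))
        mass = (2 * math.pi * sigma**2) ** 1.5
        assert g.integral() == pytest.approx(12 * mass, rel=0.01)

    def test_half_maximum_at_half_fwhm(self):
        """Value at r = FWHM/2 from an atom is half the peak (that is the
        definition of treating resolution as FWHM)."""
        sys = make_ring_channel([RingSpec(0.0, 5.0, 1, 1.5)])
        g = synthetic_density(sys, resolution=4.0, spacing=0.25)
        atom = sys.positions[0]
        idx_peak = np.round((atom - g.origin) / g.spacing).astype(int)
        peak = g.values[tuple(idx_peak)]
        off = atom + np.array([2.0, 0.0, 0.0])  # FWHM/2 for resolution 4
        idx_off = np.round((off - g.origin) / g.spacing).astype(int)
        assert g.values[tuple(idx_off)] == pytest.approx(0.5 * peak, rel=0.05)

    def test_translation_equivariance(self):
        sys = make_ring_channel([RingSpec(0.0, 5.0, 12, 1.5)])
        shift = np.array([3.0, -2.0, 5.0])
        moved = sys.with_positions(sys.positions + shift)
        g0 = synthetic_density(sys, resolution=4.0, spacing=0.5)
        g1 = synthetic_density(moved, resolution=4.0, spacing=0.5)
        assert np.allclose(g1.peak_position() - g0.peak_position(), shift, atol=0.5)

    def test_empty_system_errors(self, single_ring):
        empty = single_ring.subset(np.zeros(single_ring.n_atoms, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            synthetic_density(empty, resolution=4.0, spacing=1.0)

    def test_ccp4_round_trip(self, tmp_path, single_ring):
        import gemmi

        g = synthetic_density(single_ring, resolution=4.0, spacing=1.0)
        p = tmp_path / "map.ccp4"
        g.write_ccp4(p)
        m = gemmi.read_ccp4_map(str(p))
        assert np.allclose(np.array(m.grid), g.values, atol=1e-4)
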