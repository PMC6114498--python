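"""Synthetic phantom generators: HU profile, brush painting, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasctree import phantoms
from vasctree.phantoms import (ABZ_RANGES, ABZParams, PhantomSpec,
                               enumerate_model_grid, hu_profile,
                               make_bifurcation, make_helix, make_torus,
                               paint_brush, sample_abz)


class TestHUProfile:
    def test_boundary_value_is_exactly_C(self):
        for C, R, a in [(150, 5, 10), (100, 1.3, 2), (300, 0.7, 7)]:
            assert hu_profile(R, C, R, a) == pytest.approx(C, abs=1e-12)

    def test_axis_and_far_field_limits(self):
        assert hu_profile(0.0, 150, 5, 10) == pytest.approx(225, abs=1e-12)
        assert hu_profile(1e9, 150, 5, 10) == pytest.approx(75, abs=1e-9)

    @given(r=st.floats(0, 50), C=st.floats(50, 500), R=st.floats(0.2, 10),
           a=st.floats(0.5, 20))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, r, C, R, a):
        v = hu_profile(r, C, R, a)
        # open bounds analytically; the sigmoid saturates in float64
        assert C / 2 <= v <= 1.5 * C
        assert hu_profile(r + 0.7, C, R, a) <= v + 1e-9

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            hu_profile(1.0, 150, -1, 10)
        with pytest.raises(ValueError):
            hu_profile(1.0, 150, 5, 0)


class TestBrush:
    def test_idempotent_and_max_compose(self):
        vol = phantoms.blank_volume(20, 0.5)
        c = np.array([10.0, 10.0, 10.0])
        paint_brush(vol, c, R=2.0)
        once = vol.data.copy()
        paint_brush(vol, c, R=2.0)
        np.testing.assert_array_equal(vol.data, once)

        a = phantoms.blank_volume(20, 0.5)
        paint_brush(a, [8, 10, 10], R=2.0)
        only_a = a.data.copy()
        b = phantoms.blank_volume(20, 0.5)
        paint_brush(b, [11, 10, 10], R=2.0)
        both = phantoms.blank_volume(20, 0.5)
        paint_brush(both, [8, 10, 10], R=2.0)
        paint_brush(both, [11, 10, 10], R=2.0)
        np.testing.assert_allclose(both.data,
                                   np.maximum(only_a, b.data), rtol=0, atol=0)

    def test_voxel_at_radius_R_gets_boundary_value(self):
        vol = phantoms.blank_volume(20, 0.5)
        # center on a voxel center so a voxel sits exactly R away on-axis
        c = vol.to_physical([20, 20, 20])
        paint_brush(vol, c, R=2.0, C=150.0, a=10.0)
        probe = vol.to_physical([24, 20, 20])   # 4 voxels * 0.5 mm = R
        i = tuple(np.round(vol.to_index(probe)).astype(int))
        assert vol.data[i] == pytest.approx(150.0, abs=1e-4)

    def test_outside_center_warns_and_is_noop(self):
        vol = phantoms.blank_volume(20, 0.5)
        before = vol.data.copy()
        with pytest.warns(UserWarning):
            paint_brush(vol, [100, 0, 0], R=2.0)
        np.testing.assert_array_equal(vol.data, before)


class TestSweptModels:
    def test_torus_centerline_and_background_values(self, small_torus):
        vol, gt = small_torus
        from vasctree.volume import TricubicSampler
        s = TricubicSampler(vol)
        on_axis = s(gt.curve(np.linspace(0, gt.length, 7)))
        assert np.all(np.abs(on_axis - 225.0) < 2.0)
        corner = vol.origin + 1.0
        assert abs(float(s(corner)) - 75.0) < 1.0

    def test_torus_radius_recovered_by_distance_map(self, small_torus):
        vol, gt = small_torus
        from vasctree.volume_ops import distance_map, segment_threshold
        dm = distance_map(segment_threshold(vol, 150.0))
        assert abs(float(dm.data.max()) - 2.0) <= 0.6

    def test_torus_does_not_fit_raises(self):
        with pytest.raises(ValueError):
            make_torus(4.0, 49.0)

    def test_helix_ground_truth_closed_forms(self):
        D, R1, R2 = 2.0, 20.0, 30.0
        vol, gt = make_helix(D, R1, R2)
        b = R2 / (2 * np.pi)
        assert gt.curvature == pytest.approx(R1 / (R1**2 + b**2), rel=1e-12)
        assert gt.torsion == pytest.approx(b / (R1**2 + b**2), rel=1e-12)
        # chordal arc length of the sampled truth matches the closed form
        pts = gt.sample(0.05)
        chord = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert chord == pytest.approx(gt.length, rel=1e-3)

    def test_flat_helix_degenerates_to_torus(self):
        _, gt = make_helix(2.0, 15.0, 0.0)
        assert gt.curvature == pytest.approx(1 / 15.0, rel=1e-12)
        assert gt.torsion == 0.0

    def test_torus_distance_closed_form(self, small_torus):
        _, gt = small_torus
        rng = np.random.default_rng(0)
        pts = gt.curve(rng.uniform(0, gt.length, 5))
        offs = rng.normal(size=(5, 3))
        offs /= np.linalg.norm(offs, axis=1, keepdims=True)
        d = gt.distance_to(pts + 0.7 * offs)
        assert np.all(d <= 0.7 + 1e-9)
        np.testing.assert_allclose(gt.distance_to(pts), 0, atol=1e-9)


class TestModelGrid:
    def test_rejection_rule_counts(self):
        d5 = enumerate_model_grid("torus", (5, 5, 1), (5, 30, 1))
        assert len(d5) == 21          # R1 in 10..30 survive R1 >= 2D
        d1 = enumerate_model_grid("torus", (1, 1, 1), (5, 30, 1))
        assert len(d1) == 26

    def test_full_torus_grid_against_brute_force(self):
        grid = enumerate_model_grid("torus", (1, 5, 0.25), (5, 30, 1))
        brute = [(d / 4, r) for d in range(4, 21) for r in range(5, 31)
                 if r >= 2 * (d / 4)]
        assert len(brute) == len(grid)
        assert [(s.D, s.R1) for s in grid] == [(d, float(r))
                                               for d, r in brute]
        raw = 17 * 26
        assert raw == 442

    def test_helix_grid_rejects_both_rules(self):
        grid = enumerate_model_grid("helix", (1.5, 4, 0.25), (5, 30, 1),
                                    (5, 9, 1))
        assert all(s.R1 >= 2 * s.D and s.R2 >= 2 * s.D for s in grid)
        brute = sum(1 for d in range(6, 17) for r1 in range(5, 31)
                    for r2 in range(5, 10)
                    if r1 >= 2 * (d / 4) and r2 >= 2 * (d / 4))
        assert len(grid) == brute

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec("torus", D=4.0, R1=5.0)
        with pytest.raises(ValueError):
            PhantomSpec("helix", D=2.0, R1=10.0, R2=1.0)


class TestBifurcationPhantom:
    def test_symmetric_construction_angles(self):
        p = ABZParams(A1=45, A2=45, A1_pl=0, A2_pl=0)
        _, gt = make_bifurcation(p)
        assert gt.ba == pytest.approx(90.0, abs=1e-9)
        np.testing.assert_allclose(gt.va, [45.0, 45.0], atol=1e-9)

    def test_in_plane_construction_gives_coi_zero_branches(self):
        p = ABZParams(A1=30, A2=60, A1_pl=0, A2_pl=0)
        _, gt = make_bifurcation(p)
        # branch vectors lie in the division plane -> perpendicular to DPN
        for d in gt.branch_dirs:
            assert abs(np.dot(d, gt.dpn)) < 1e-12
        np.testing.assert_allclose(gt.coi_branches, 0.0, atol=1e-12)

    def test_angles_recompute_from_stored_vectors(self):
        p = sample_abz(1, seed=5)[0]
        _, gt = make_bifurcation(p)
        d1, d2 = gt.branch_dirs
        ba = np.degrees(np.arccos(np.clip(np.dot(d1, d2), -1, 1)))
        assert ba == pytest.approx(gt.ba, abs=1e-9)
        for i, d in enumerate(gt.branch_dirs):
            va = np.degrees(np.arccos(np.clip(np.dot(gt.trunk_dir, d), -1, 1)))
            assert va == pytest.approx(gt.va[i], abs=1e-9)

    def test_out_of_range_warns_not_raises(self):
        with pytest.warns(UserWarning):
            ABZParams(A1=5.0, A2=45.0)


class TestSampleABZ:
    def test_bounds_and_count(self):
        draws = sample_abz(70, seed=3)
        assert len(draws) == 70
        for p in draws:
            for name, (lo, hi) in ABZ_RANGES.items():
                assert lo <= getattr(p, name) <= hi

    def test_reproducible_and_degenerate(self):
        assert sample_abz(5, seed=9) == sample_abz(5, seed=9)
        one = sample_abz(1, ranges={"wAn": (0.1, 0.1)}, seed=0)[0]
        assert one.wAn == 0.1
        with pytest.raises(ValueError):
            sample_abz(0)
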