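"""Division-zone construction, angles and coplanarity indices."""

import numpy as np
import pytest

from vasctree.bifurcation import (BifurcationZone, ZoneConfig, analyze_zone,
                                  angles, build_zone, coplanarity_index,
                                  division_plane, find_split_point,
                                  select_true_division, zone_from_curves)
from vasctree.centerline import Centerline


def polyline(pts):
    return Centerline.from_points(np.asarray(pts, dtype=float),
                                  np.ones(len(pts)))


def v_curves(apex_z=5.0, spread=1.0, n=40):
    """Two curves sharing a straight stem, diverging as a V at apex_z."""
    z = np.linspace(0, 10, n)
    x = np.where(z > apex_z, (z - apex_z) * spread, 0.0)
    a = polyline(np.stack([x, np.zeros(n), z], axis=1))
    b = polyline(np.stack([-x, np.zeros(n), z], axis=1))
    return a, b


class TestSplitPoint:
    def test_v_apex_found(self):
        a, b = v_curves()
        T0, ia, ib = find_split_point(a, b, ZoneConfig())
        assert abs(T0[2] - 5.0) <= 10 / 39 + 1e-9
        assert abs(T0[0]) < 0.2

    def test_never_close_raises(self):
        a = polyline([[0, 0, 0], [0, 0, 5]])
        b = polyline([[3, 0, 0], [3, 0, 5]])
        with pytest.raises(ValueError, match="no division"):
            find_split_point(a, b)

    def test_identical_curves_raise(self):
        a, _ = v_curves()
        with pytest.raises(ValueError, match="degenerate"):
            find_split_point(a, a)

    def test_monotone_in_d(self):
        a, b = v_curves()
        zs = []
        for d in (0.1, 0.2, 0.4, 0.8):
            T0, *_ = find_split_point(a, b, ZoneConfig(d=d))
            zs.append(T0[2])
        assert all(z2 >= z1 - 1e-9 for z1, z2 in zip(zs, zs[1:]))


class TestBuildZone:
    def test_symmetric_branch_starts(self):
        a, b = v_curves()
        zone = zone_from_curves(a, b, ZoneConfig(point_spacing_factor=1.0))
        d1 = np.linalg.norm(zone.Br1[0] - zone.T0)
        d2 = np.linalg.norm(zone.Br2[0] - zone.T0)
        assert abs(d1 - d2) <= 10 / 39 + 1e-9

    def test_minimal_point_count(self):
        a, b = v_curves()
        zone = zone_from_curves(a, b, ZoneConfig(n_points=2))
        assert len(zone.Tr) == 2 and len(zone.Br1) == 2

    def test_zone_angles_match_construction(self):
        a, b = v_curves(spread=1.0)     # branches at 45 deg from z
        zone = analyze_zone(zone_from_curves(a, b))
        assert zone.BA == pytest.approx(90.0, abs=2.0)
        np.testing.assert_allclose(zone.VA, [45.0, 45.0], atol=2.0)


class TestDivisionPlane:
    def make_zone(self, tr0, br1_0, br2_0):
        tr = np.array([tr0, tr0 - np.array([0, 0, 2.0])])
        return BifurcationZone(np.asarray(tr0, float), tr,
                               np.array([br1_0, br1_0]),
                               np.array([br2_0, br2_0]),
                               np.ones(2), np.ones(2), np.ones(2))

    def test_planar_points_give_axis_normal(self):
        z = self.make_zone([0, 0, 0.0], [1, 0, 0.0], [0, 1, 0.0])
        _, n = division_plane(z)
        np.testing.assert_allclose(np.abs(n), [0, 0, 1], atol=1e-12)

    def test_collinear_raises(self):
        z = self.make_zone([0, 0, 0.0], [1, 0, 0.0], [2, 0, 0.0])
        with pytest.raises(ValueError, match="degenerate plane"):
            division_plane(z)


class TestAnglesAndCoI:
    def test_vector_arithmetic(self):
        s = 1 / np.sqrt(2)
        tr = np.array([[0, 0, 0.0], [0, 0, -1.0]])
        br1 = np.array([[0, 0, 0.0], [s, 0, s]])
        br2 = np.array([[0, 0, 0.0], [-s, 0, s]])
        zone = BifurcationZone(np.zeros(3), tr, br1, br2,
                               np.ones(2), np.ones(2), np.ones(2))
        ba, va1, va2 = angles(zone)
        assert ba == pytest.approx(90.0, abs=1e-9)
        assert va1 == pytest.approx(45.0, abs=1e-9)
        assert va2 == pytest.approx(45.0, abs=1e-9)

    @pytest.mark.parametrize("v,expected", [
        ([0, 0, 1.0], 1.0),       # parallel to the normal
        ([1, 0, 0.0], 0.0),       # in the division plane
        ([1, 0, 1.0], 0.5),       # 45 degrees
        ([0, 0, -1.0], 1.0),      # obtuse angle folds acute
    ])
    def test_coplanarity_index_cases(self, v, expected):
        assert coplanarity_index(np.array(v), np.array([0, 0, 1.0])) == \
            pytest.approx(expected, abs=1e-12)

    def test_inverted_convention(self):
        v = np.array([1, 0, 1.0])
        lit = coplanarity_index(v, np.array([0, 0, 1.0]))
        inv = coplanarity_index(v, np.array([0, 0, 1.0]),
                                convention="in_plane")
        assert lit + inv == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            coplanarity_index(np.zeros(3), np.array([0, 0, 1.0]))

    def test_rigid_motion_invariance(self):
        a, b = v_curves(spread=0.7)
        zone = analyze_zone(zone_from_curves(a, b))
        # random rotation + translation applied to the raw curves
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        t = rng.normal(size=3) * 10
        ar = polyline(a.points @ Q.T + t)
        br = polyline(b.points @ Q.T + t)
        zr = analyze_zone(zone_from_curves(ar, br))
        assert zr.BA == pytest.approx(zone.BA, abs=1e-6)
        np.testing.assert_allclose(zr.VA, zone.VA, atol=1e-6)


class TestSelectTrueDivision:
    def zone_at(self, z, types):
        tr = np.array([[0, 0, z], [0, 0, z - 2.0]])
        br1 = np.array([[0.1, 0, z], [1, 0, z + 1.0]])
        br2 = np.array([[-0.1, 0, z], [-1, 0, z + 1.0]])
        return BifurcationZone(np.array([0, 0, float(z)]), tr, br1, br2,
                               np.ones(2), np.ones(2), np.ones(2),
                               curve_types=types)

    def test_single_zone_returned_unchanged(self):
        z = self.zone_at(10, (2, 3))
        div, an = select_true_division([z], np.zeros(3))
        assert div is z and an is None

    def test_aneurysm_zone_flagged_division_returned(self):
        near = self.zone_at(10, (2, 3))
        far = self.zone_at(18, (1, 2))
        div, an = select_true_division([near, far], np.zeros(3))
        assert div is near and an is far

    def test_all_aneurysm_curves_raise(self):
        z = self.zone_at(10, (1, 1))
        with pytest.raises(ValueError):
            select_true_division([z], np.zeros(3))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_true_division([], np.zeros(3))
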