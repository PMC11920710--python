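"""Centerline construction and structured surface sampling."""

import math

import numpy as np
import pytest

import tawssnet as tn
from tawssnet.geometry import (
    GeometryConfig,
    GeometryError,
    VESSEL_CODES,
    apply_pose,
    blended_distance,
    build_centerlines,
    sample_surface,
)
from tawssnet.morphology import MorphologyParams


def _params(**kw):
    base = dict(d_lm=3.0, d_lcx=2.2, d_lad=2.6, gamma=150.0, alpha=70.0, model_id="t")
    base.update(kw)
    return MorphologyParams(**base)


class TestCenterlines:
    def test_lm_is_straight_into_origin(self):
        cls = build_centerlines(_params())
        lm = cls["LM"]
        assert np.allclose(lm.points[-1], [0, 0, 0])
        assert np.allclose(lm.tangents, [[1, 0, 0], [1, 0, 0]])

    @pytest.mark.parametrize("gamma", [112.75, 150.0, 172.75])
    def test_gamma_recovered_from_tangents(self, gamma):
        cls = build_centerlines(_params(gamma=gamma))
        t_lad = cls["LAD"].tangents[0]
        minus_lm = -cls["LM"].tangents[-1]
        ang = math.degrees(math.acos(np.clip(np.dot(minus_lm, t_lad), -1, 1)))
        assert abs(ang - gamma) < 1e-6

    @pytest.mark.parametrize("alpha", [15.0, 70.0, 130.0])
    def test_alpha_recovered_from_tangents(self, alpha):
        cls = build_centerlines(_params(alpha=alpha))
        t_lad, t_lcx = cls["LAD"].tangents[0], cls["LCX"].tangents[0]
        ang = math.degrees(math.acos(np.clip(np.dot(t_lad, t_lcx), -1, 1)))
        assert abs(ang - alpha) < 1e-6

    def test_near_straight_continuation_at_upper_gamma(self):
        cls = build_centerlines(_params(gamma=172.75))
        t_lad = cls["LAD"].tangents[0]
        # LAD initial tangent deviates only 7.25 deg from +x
        assert math.degrees(math.acos(np.dot(t_lad, [1, 0, 0]))) == pytest.approx(7.25, abs=1e-6)

    def test_infinite_arc_radius_gives_straight_daughters(self):
        cfg = GeometryConfig(arc_radius=math.inf)
        cls = build_centerlines(_params(), cfg)
        for v in ("LAD", "LCX"):
            t = cls[v].tangents
            assert np.allclose(t, t[0], atol=1e-12)

    def test_random_draws_angle_recovery(self):
        for p in tn.sample_morphologies(tn.TABLE_RANGES, 100, seed=11):
            cls = build_centerlines(p)
            t_lad, t_lcx = cls["LAD"].tangents[0], cls["LCX"].tangents[0]
            g = math.degrees(math.acos(np.clip(np.dot([-1, 0, 0], t_lad), -1, 1)))
            a = math.degrees(math.acos(np.clip(np.dot(t_lad, t_lcx), -1, 1)))
            assert abs(g - p.gamma) < 1e-6
            assert abs(a - p.alpha) < 1e-6

    def test_foldback_configuration_rejected(self):
        cfg = GeometryConfig(fold_threshold_deg=30.0)
        # alpha = 160 deg (outside the admissible table) with a near-straight
        # LAD sends the LCx heading within 30 deg of the upstream LM direction
        with pytest.raises(GeometryError, match="folds back"):
            build_centerlines(_params(gamma=172.75, alpha=160.0), cfg)


class TestSurface:
    def test_point_budget(self, morphs):
        cls = build_centerlines(morphs[0])
        cloud = sample_surface(cls, morphs[0], 64, 64)
        assert cloud.n_points == 4096
        assert cloud.coords.shape == (4096, 3)

    def test_implicit_residual_below_tolerance(self, morphs):
        p = morphs[2]
        cls = build_centerlines(p)
        cloud = sample_surface(cls, p, 32, 32)
        f = blended_distance(cloud.coords, cls, 0.4 * p.d_lm)
        assert np.abs(f).max() < 1e-6

    def test_pure_tube_station_has_vessel_diameter(self, morphs):
        p = morphs[0]
        cls = build_centerlines(p)
        cloud = sample_surface(cls, p, 64, 64)
        # first LM station: far from the junction (LM spans 16 rows)
        pts = cloud.coords[cloud.station_index == 0]
        d = 2.0 * cls["LM"].distance(pts)
        assert np.allclose(d, p.d_lm, atol=1e-6)

    def test_diameter_recovery_by_circle_fit(self, morphs):
        p = morphs[3]
        cls = build_centerlines(p)
        cloud = sample_surface(cls, p, 64, 64)
        for row, vessel in ((1, "LM"), (35, "LAD")):
            pts = cloud.coords[cloud.station_index == row]
            centroid = pts.mean(axis=0)
            r_fit = np.linalg.norm(pts - centroid, axis=1).mean()
            d_true = {"LM": p.d_lm, "LAD": p.d_lad}[vessel]
            assert abs(2 * r_fit - d_true) / d_true < 1e-3

    def test_row_and_angle_bookkeeping(self, labeled_small):
        cloud, _ = labeled_small
        assert cloud.rows == 16 and cloud.cols == 16
        assert set(cloud.station_index) == set(range(16))
        angles = cloud.circ_angle[cloud.station_index == 0]
        assert np.allclose(angles, 2 * np.pi * np.arange(16) / 16)

    def test_junction_labels_present_near_origin(self, morphs):
        p = morphs[0]
        cls = build_centerlines(p)
        cloud = sample_surface(cls, p, 32, 32)
        j = cloud.vessel_label == VESSEL_CODES["JUNCTION"]
        assert j.any()
        # junction points cluster near the centerline meeting point
        assert np.linalg.norm(cloud.coords[j], axis=1).max() < 6.0 * p.d_lm

    def test_rigid_motion_equivariance(self, morphs):
        p = morphs[1]
        cls = build_centerlines(p)
        cloud = sample_surface(cls, p, 16, 16)
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = np.array([5.0, -2.0, 1.0])
        moved = apply_pose(cloud.coords, rot, t)
        direct = cloud.coords @ rot.T + t
        assert np.abs(moved - direct).max() < 1e-9
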