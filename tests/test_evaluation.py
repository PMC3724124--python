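"""Spatial metric, interpolating-spline resampling and connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from splinetrack.evaluation import (
    connectivity_score,
    fiber_l2_distance,
    resample_interpolating,
    score_against_truth,
    step_length_sweep,
)
from splinetrack.io_formats import Fiber, Tractogram


def _tg(fibers, voxel_size=1.0):
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    return Tractogram(list(fibers), np.diag(list(vs) + [1.0]), vs)


class TestResampleInterpolating:
    def test_two_point_fiber_gives_equally_spaced_line(self):
        fib = Fiber([[0, 0, 0], [10, 0, 0]])
        out = resample_interpolating(fib, s=1000)
        assert len(out) == 1000
        np.testing.assert_allclose(np.diff(out.points[:, 0]), 10 / 999, atol=1e-9)
        np.testing.assert_allclose(out.points[:, 1:], 0.0, atol=1e-12)

    def test_straight_1000_point_fiber_unchanged(self):
        pts = np.column_stack([np.linspace(0, 10, 1000), np.zeros(1000), np.zeros(1000)])
        out = resample_interpolating(Fiber(pts), s=1000)
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(0.2, 1.0, (12, 3)), axis=0)
        out = resample_interpolating(Fiber(pts), s=333)
        np.testing.assert_array_equal(out.points[0], pts[0])
        np.testing.assert_array_equal(out.points[-1], pts[-1])

    def test_quarter_circle_close_to_analytic_arc(self):
        R = 10.0
        ang = np.linspace(0, np.pi / 2, 10)
        pts = np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros(10)])
        out = resample_interpolating(Fiber(pts), s=500)
        radii = np.linalg.norm(out.points[:, :2], axis=1)
        assert np.abs(radii - R).max() < 0.01 * R


class TestL2Distance:
    def test_self_distance_zero(self):
        fib = Fiber(np.cumsum(np.random.default_rng(1).uniform(0.1, 1, (20, 3)), axis=0))
        assert fiber_l2_distance(fib, fib) == 0.0

    def test_parallel_offset_is_exactly_d(self):
        pts = np.column_stack([np.linspace(0, 20, 50), np.zeros(50), np.zeros(50)])
        d = 3.7
        assert fiber_l2_distance(Fiber(pts), Fiber(pts + [0, d, 0])) == pytest.approx(d)

    def test_reversed_copy_distance_zero(self):
        pts = np.cumsum(np.random.default_rng(2).uniform(0.1, 1, (30, 3)), axis=0)
        assert fiber_l2_distance(Fiber(pts), Fiber(pts[::-1])) == pytest.approx(0.0, abs=1e-9)

    def test_voxel_size_converts_to_mm(self):
        pts = np.column_stack([np.linspace(0, 20, 50), np.zeros(50), np.zeros(50)])
        d = fiber_l2_distance(Fiber(pts), Fiber(pts + [0, 1.0, 0]), voxel_size=3.0)
        assert d == pytest.approx(3.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=hst.integers(0, 10_000))
    def test_pseudo_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        fibers = [
            Fiber(np.cumsum(rng.uniform(0.05, 1.0, (rng.integers(5, 25), 3)), axis=0))
            for _ in range(3)
        ]
        s = 200
        dab = fiber_l2_distance(fibers[0], fibers[1], s)
        dba = fiber_l2_distance(fibers[1], fibers[0], s)
        dac = fiber_l2_distance(fibers[0], fibers[2], s)
        dcb = fiber_l2_distance(fibers[2], fibers[1], s)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-9)
        assert dab <= dac + dcb + 1e-9


class TestConnectivity:
    SHAPE = (30, 10, 3)

    def _roi(self, center):
        roi = np.zeros(self.SHAPE, bool)
        roi[center] = True
        return roi

    def test_endpoint_connection_counts(self):
        roi_a = self._roi((2, 5, 1))
        roi_b = self._roi((27, 5, 1))
        fib = Fiber(np.column_stack([np.linspace(2, 27, 40),
                                     np.full(40, 5.0), np.ones(40)]))
        counts, n = connectivity_score(_tg([fib]), [(roi_a, roi_b)])
        assert counts == [1] and n == 1

    def test_pass_through_without_terminal_points_does_not_count(self):
        roi_a = self._roi((10, 5, 1))
        roi_b = self._roi((20, 5, 1))
        fib = Fiber(np.column_stack([np.linspace(2, 27, 40),
                                     np.full(40, 5.0), np.ones(40)]))
        counts, n = connectivity_score(_tg([fib]), [(roi_a, roi_b)])
        assert counts == [0] and n == 0
        counts_pt, n_pt = connectivity_score(
            _tg([fib]), [(roi_a, roi_b)], mode="passthrough"
        )
        assert counts_pt == [1] and n_pt == 1

    def test_overlapping_pair_warns(self):
        roi = self._roi((5, 5, 1))
        fib = Fiber([[4, 5, 1], [6, 5, 1]])
        with pytest.warns(UserWarning, match="overlap"):
            connectivity_score(_tg([fib]), [(roi, roi)])


class TestScoreAgainstTruth:
    SHAPE = (30, 10, 3)

    def _setup(self):
        truth = Fiber(np.column_stack([np.linspace(2, 27, 26),
                                       np.full(26, 5.0), np.ones(26)]))
        roi_a = np.zeros(self.SHAPE, bool); roi_a[1:4, 4:7, :] = True
        roi_b = np.zeros(self.SHAPE, bool); roi_b[26:29, 4:7, :] = True
        return truth, (roi_a, roi_b)

    def test_truth_against_itself_scores_zero(self):
        truth, pair = self._setup()
        scores, grand = score_against_truth(_tg([truth]), [truth], [pair])
        assert grand == pytest.approx(0.0, abs=1e-9)
        assert scores[0].connected and scores[0].n_candidates == 1

    def test_uniform_shift_scores_exactly_one_voxel(self):
        truth, pair = self._setup()
        shifted = Fiber(truth.points + [0.0, 1.0, 0.0])
        scores, grand = score_against_truth(_tg([shifted]), [truth], [pair])
        assert grand == pytest.approx(1.0, abs=1e-9)

    def test_distance_reported_in_mm(self):
        truth, pair = self._setup()
        shifted = Fiber(truth.points + [0.0, 1.0, 0.0])
        _, grand = score_against_truth(
            _tg([shifted], voxel_size=3.0), [truth], [pair]
        )
        assert grand == pytest.approx(3.0, abs=1e-9)

    def test_unmatched_bundle_reported_not_scored(self):
        truth, pair = self._setup()
        far = Fiber(np.column_stack([np.linspace(2, 27, 26),
                                     np.full(26, 8.0), np.full(26, 2.0)]))
        scores, grand = score_against_truth(_tg([far]), [truth], [pair])
        assert not scores[0].connected
        assert np.isnan(scores[0].mean_l2) and np.isnan(grand)

    def test_grand_mean_invariant_to_fiber_order_and_reversal(self):
        truth, pair = self._setup()
        f1 = Fiber(truth.points + [0.0, 0.5, 0.0])
        f2 = Fiber(truth.points + [0.0, -0.5, 0.0])
        _, g1 = score_against_truth(_tg([f1, f2]), [truth], [pair])
        _, g2 = score_against_truth(
            _tg([Fiber(f2.points[::-1]), f1]), [truth], [pair]
        )
        assert g1 == pytest.approx(g2, abs=1e-9)


class TestStepLengthSweep:
    def test_single_h_gives_one_row(self):
        truth = Fiber(np.column_stack([np.linspace(2, 27, 26),
                                       np.full(26, 5.0), np.ones(26)]))
        roi_a = np.zeros((30, 10, 3), bool); roi_a[1:4, 4:7, :] = True
        roi_b = np.zeros((30, 10, 3), bool); roi_b[26:29, 4:7, :] = True
        table = step_length_sweep(
            [1.0], lambda h: _tg([truth]), [truth], [(roi_a, roi_b)]
        )
        assert len(table) == 1
        assert table.loc[0, "grand_mean_l2_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_straight_phantom_near_equal_across_h(self, straight_phantom):
        import splinetrack as st

        dwi = straight_phantom["dwi"]
        truth = straight_phantom["truth"]
        rois = straight_phantom["rois"]

        def track(h):
            params = st.TrackingParams(h=h, min_length=10.0)
            return st.track_wholefield(
                rois[0][0] | rois[0][1], straight_phantom["fa"], params,
                odf=straight_phantom["odf"], method="spline",
                voxel_size=dwi.voxel_size, affine=dwi.affine,
            )

        table = step_length_sweep([2.0, 1.0], track, truth, rois)
        d = table["grand_mean_l2_mm"].to_numpy()
        assert np.all(np.isfinite(d))
        assert abs(d[0] - d[1]) < 0.5  # no curvature to resolve
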