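"""B-spline segment math and the iterative spline tracker."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import splinetrack as st
from splinetrack.exceptions import ValidationError
from splinetrack.spline_tracker import (
    BSPLINE_BASIS,
    TrackingParams,
    _run_direction,
    bspline_segment,
    final_smooth,
    seed_initialize,
    step_direction,
)
from splinetrack.synthetic_data import odf_field_from_directions
from splinetrack.tensor_model import FAVolume


coords = hst.floats(-50.0, 50.0, allow_nan=False)
point = hst.tuples(coords, coords, coords).map(np.array)


class TestBsplineSegment:
    def test_basis_rows_partition_of_unity(self):
        u = np.linspace(0.0, 1.0, 101)
        U = np.column_stack([u**3, u**2, u, np.ones_like(u)])
        weights = U @ BSPLINE_BASIS
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_control_points_collapse(self):
        p = np.array([2.0, 3.0, 4.0])
        samples = bspline_segment(p, p, p, p, nu=0.1)
        np.testing.assert_allclose(samples, np.tile(p, (len(samples), 1)), atol=1e-12)

    def test_collinear_equispaced_endpoint_identity(self):
        # hand evaluation: s(0) = (0 + 4*1 + 2)/6 = 1, s(1) = (1 + 4*2 + 3)/6 = 2
        pts = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        samples = bspline_segment(*pts, nu=0.01)
        np.testing.assert_allclose(samples[0], [1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(samples[-1], [2.0, 0.0, 0.0], atol=1e-12)
        assert len(samples) == 101

    @settings(max_examples=50, derandomize=True)
    @given(p0=point, p1=point, p2=point, p3=point)
    def test_affine_invariance(self, p0, p1, p2, p3):
        A = np.array([[1.5, 0.2, 0.0], [0.0, 0.9, -0.3], [0.1, 0.0, 1.1]])
        t = np.array([3.0, -2.0, 7.0])
        direct = bspline_segment(p0, p1, p2, p3, nu=0.05)
        mapped = bspline_segment(*(A @ p + t for p in (p0, p1, p2, p3)), nu=0.05)
        np.testing.assert_allclose(mapped, direct @ A.T + t, atol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(p0=point, p1=point, p2=point, p3=point)
    def test_samples_inside_convex_hull(self, p0, p1, p2, p3):
        ctrl = np.array([p0, p1, p2, p3])
        samples = bspline_segment(p0, p1, p2, p3, nu=0.05)
        # basis weights are nonnegative on [0,1] and sum to 1, so every
        # sample is a convex combination; verify via bounding planes
        lo = ctrl.min(axis=0) - 1e-9
        hi = ctrl.max(axis=0) + 1e-9
        assert (samples >= lo).all() and (samples <= hi).all()

    def test_too_few_control_points_contract_error(self):
        with pytest.raises((ValidationError, TypeError), match="control points|argument"):
            bspline_segment(
                np.zeros(3), np.ones(3), np.full(3, 2.0), np.array([[0, 0, 0]] * 2), 0.1
            )


class TestStepDirection:
    def _odf(self, axes):
        dirs = np.empty((3, 3, 3), dtype=object)
        for ijk in np.ndindex((3, 3, 3)):
            dirs[ijk] = np.asarray(axes, float).reshape(-1, 3)
        return odf_field_from_directions(dirs)

    def test_aligned_axis_kept(self):
        odf = self._odf([[1, 0, 0]])
        d = step_direction(odf, (1, 1, 1), np.array([1.0, 0, 0]))
        np.testing.assert_allclose(d, [1, 0, 0])

    def test_sign_resolved_against_incoming(self):
        odf = self._odf([[1, 0, 0]])
        d = step_direction(odf, (1, 1, 1), np.array([-1.0, 0, 0]))
        np.testing.assert_allclose(d, [-1, 0, 0])

    def test_best_of_four_signed_candidates(self):
        odf = self._odf([[1, 0, 0], [0, 1, 0]])
        incoming = np.array([0.94, 0.34, 0.0])
        incoming /= np.linalg.norm(incoming)
        d = step_direction(odf, (1, 1, 1), incoming)
        # brute force over the 4 signed candidates
        cands = [s * np.array(a, float) for a in ([1, 0, 0], [0, 1, 0]) for s in (1, -1)]
        best = max(cands, key=lambda c: c @ incoming)
        np.testing.assert_allclose(d, best)

    def test_outside_volume_returns_none(self):
        odf = self._odf([[1, 0, 0]])
        assert step_direction(odf, (99, 0, 0), np.array([1.0, 0, 0])) is None

    def test_empty_maxima_returns_none(self):
        odf = self._odf(np.zeros((0, 3)))
        assert step_direction(odf, (1, 1, 1), np.array([1.0, 0, 0])) is None


class TestSeedInitialize:
    def test_uniform_field_control_points(self, uniform_x_field):
        odf, fa = uniform_x_field
        state = seed_initialize((10, 4, 2), odf, fa, TrackingParams(h=1.0))
        np.testing.assert_allclose(state.control[0], [9, 4, 2], atol=1e-12)
        np.testing.assert_allclose(state.control[1], [10, 4, 2], atol=1e-12)
        np.testing.assert_allclose(state.control[2], [11, 4, 2], atol=1e-12)
        np.testing.assert_allclose(state.control[3], [12, 4, 2], atol=1e-12)

    def test_zero_fa_seed_rejected(self, uniform_x_field):
        odf, _ = uniform_x_field
        fa0 = FAVolume(np.zeros(odf.spatial_shape), np.ones(odf.spatial_shape, bool))
        assert seed_initialize((10, 4, 2), odf, fa0, TrackingParams()) is None

    def test_curved_field_bends_p3_toward_curve(self):
        # quarter-circle tangent field: p3 must leave the p1->p2 line
        shape = (40, 40, 3)
        C = np.array([5.0, 5.0, 1.0])
        dirs = np.empty(shape, dtype=object)
        for ijk in np.ndindex(shape):
            v = np.array(ijk, float) - C
            r = np.linalg.norm(v[:2])
            if r < 1e-6:
                dirs[ijk] = np.zeros((0, 3))
                continue
            t = np.array([-v[1], v[0], 0.0]) / r
            dirs[ijk] = t[None, :]
        odf = odf_field_from_directions(dirs)
        fa = FAVolume(np.full(shape, 0.8), np.ones(shape, bool))
        state = seed_initialize((25, 5, 1), odf, fa, TrackingParams(h=2.0))
        p1, p2, p3 = state.control[1:]
        chord = (p2 - p1) / np.linalg.norm(p2 - p1)
        off = (p3 - p2) - ((p3 - p2) @ chord) * chord
        assert np.linalg.norm(off) > 0.05
        # deviation points toward the curve center (inward normal)
        inward = np.zeros(3)
        inward[:2] = (C - p2)[:2] / np.linalg.norm((C - p2)[:2])
        assert off @ inward > 0


class TestAdvanceAndTermination:
    def test_uniform_field_advances_about_h_per_iteration(self, uniform_x_field):
        odf, fa = uniform_x_field
        params = TrackingParams(h=1.0, min_length=0.0)
        state = seed_initialize((5, 4, 2), odf, fa, params)
        ends = []
        from splinetrack.spline_tracker import advance

        for _ in range(20):
            advance(state, odf, fa, params)
            ends.append(state.control[1][0])
        steps = np.diff(ends)
        np.testing.assert_allclose(steps, 1.0, atol=0.05)

    def test_right_angle_corner_stops_with_angle_reason(self):
        shape = (40, 40, 3)
        dirs = np.zeros(shape + (3,))
        dirs[:20, :, :, 0] = 1.0
        dirs[20:, :, :, 1] = 1.0
        odf = odf_field_from_directions(dirs)
        fa = FAVolume(np.full(shape, 0.8), np.ones(shape, bool))
        state = _run_direction(
            (5, 20, 1), odf, fa, TrackingParams(h=1.0, min_length=0.0),
            np.ones(3), np.array([1.0, 0, 0]),
        )
        assert state.termination == "angle"

    def test_fa_ramp_stops_at_analytic_crossing_voxel(self):
        # FA(x) = 0.5 - 0.01 x crosses the 0.15 threshold at x = 35
        shape = (60, 9, 3)
        dirs = np.zeros(shape + (3,))
        dirs[..., 0] = 1.0
        odf = odf_field_from_directions(dirs)
        famap = np.tile((0.5 - 0.01 * np.arange(60))[:, None, None], (1, 9, 3))
        fa = FAVolume(famap, np.ones(shape, bool))
        state = _run_direction(
            (5, 4, 1), odf, fa, TrackingParams(h=1.0, min_length=0.0),
            np.ones(3), np.array([1.0, 0, 0]),
        )
        assert state.termination == "low_fa"
        end_voxel = round(state.points[-1][0])
        assert end_voxel == 35


class TestTrackFromSeed:
    def test_straight_bundle_spans_most_of_truth(self, straight_phantom):
        dwi = straight_phantom["dwi"]
        fib = st.track_from_seed(
            (25, 5, 2), straight_phantom["odf"], straight_phantom["fa"],
            TrackingParams(h=1.0, min_length=10.0), voxel_size=dwi.voxel_size,
        )
        truth_len = straight_phantom["truth"][0].length(dwi.voxel_size)
        assert fib.length(dwi.voxel_size) >= 0.9 * truth_len
        assert np.abs(fib.points[:, 1] - 5).max() < 0.05

    def test_boundary_seed_returns_one_sided_fiber(self, straight_phantom):
        dwi = straight_phantom["dwi"]
        fib = st.track_from_seed(
            (3, 5, 2), straight_phantom["odf"], straight_phantom["fa"],
            TrackingParams(h=1.0, min_length=10.0), voxel_size=dwi.voxel_size,
        )
        assert fib is not None
        assert fib.length(dwi.voxel_size) >= 10.0

    def test_tracking_is_deterministic(self, straight_phantom):
        dwi = straight_phantom["dwi"]
        args = (
            (25, 5, 2), straight_phantom["odf"], straight_phantom["fa"],
            TrackingParams(h=1.0),
        )
        f1 = st.track_from_seed(*args, voxel_size=dwi.voxel_size)
        f2 = st.track_from_seed(*args, voxel_size=dwi.voxel_size)
        np.testing.assert_array_equal(f1.points, f2.points)

    def test_uniform_field_straightness_over_50_steps(self, uniform_x_field):
        odf, fa = uniform_x_field
        fib = st.track_from_seed(
            (5, 4, 2), odf, fa, TrackingParams(h=1.0, min_length=0.0, max_iters=50)
        )
        assert np.abs(fib.points[:, 1] - 4.0).max() < 0.05
        assert np.abs(fib.points[:, 2] - 2.0).max() < 0.05

    def test_quarter_circle_error_decreases_with_step_length(self):
        R, C = 30.0, np.array([5.0, 5.0, 1.0])
        shape = (45, 45, 3)
        dirs = np.empty(shape, dtype=object)
        famap = np.zeros(shape)
        for ijk in np.ndindex(shape):
            v = np.array(ijk, float) - C
            r = np.linalg.norm(v[:2])
            if r < 1e-6:
                dirs[ijk] = np.zeros((0, 3))
                continue
            t = np.array([-v[1], v[0], 0.0]) / r
            dirs[ijk] = t[None, :]
            famap[ijk] = 0.8 if abs(r - R) <= 3 else 0.0
        odf = odf_field_from_directions(dirs)
        fa = FAVolume(famap, np.ones(shape, bool))
        errs = []
        for h in (2.0, 1.0, 0.5):
            fib = st.track_from_seed(
                (35, 5, 1), odf, fa, TrackingParams(h=h, min_length=0.0)
            )
            rr = np.linalg.norm(fib.points[:, :2] - C[:2], axis=1)
            errs.append(np.abs(rr - R).mean())
        assert errs[0] > errs[1] > errs[2]


class TestFinalSmooth:
    def test_straight_fiber_stays_collinear(self):
        pts = np.column_stack([np.linspace(0, 40, 200), np.full(200, 3.0), np.zeros(200)])
        out = final_smooth(st.Fiber(pts), TrackingParams())
        assert np.abs(out.points[:, 1] - 3.0).max() < 1e-9
        assert np.abs(out.points[:, 2]).max() < 1e-9

    def test_short_fiber_with_stride_20_still_smooths(self):
        pts = np.column_stack([np.arange(30.0), np.zeros(30), np.zeros(30)])
        out = final_smooth(st.Fiber(pts), TrackingParams(smoothing_stride=20))
        assert len(out) >= 4
        assert "unsmoothed" not in out.flags

    def test_noisy_sinusoid_total_curvature_reduced(self):
        x = np.linspace(0, 60, 400)
        rng = np.random.default_rng(5)
        y = np.sin(x / 3.0) + rng.normal(0, 0.15, len(x))
        pts = np.column_stack([x, y, np.zeros_like(x)])

        def total_curvature(p):
            d = np.diff(p, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            dots = np.clip((d[:-1] * d[1:]).sum(1), -1, 1)
            return np.arccos(dots).sum()

        out = final_smooth(st.Fiber(pts), TrackingParams(smoothing_stride=20))
        assert total_curvature(out.points) <= total_curvature(pts)


def test_spline_resists_single_perturbed_voxel_at_least_as_well_as_euler():
    """The design motivation: one rogue dODF direction on a straight
    bundle must not deflect the spline tracker more than the Euler
    streamline through the same voxel."""
    from splinetrack.streamline_tracker import DirectionProvider, euler_track

    shape = (40, 9, 3)
    dirs = np.zeros(shape + (3,))
    dirs[..., 0] = 1.0
    rot = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0])
    dirs[20, 4, 1] = rot
    odf = odf_field_from_directions(dirs)
    fa = FAVolume(np.full(shape, 0.8), np.ones(shape, bool))
    params = TrackingParams(h=1.0, min_length=0.0)
    fs = st.track_from_seed((5, 4, 1), odf, fa, params)
    fe = euler_track((5, 4, 1), DirectionProvider.from_odf(odf), fa, params)
    dev_s = np.abs(fs.points[:, 1] - 4.0).max()
    dev_e = np.abs(fe.points[:, 1] - 4.0).max()
    assert dev_s <= dev_e + 1e-12
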