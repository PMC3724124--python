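"""Iterative cubic B-spline fiber propagation directed by dODF maxima.

Instead of chaining straight line segments and smoothing afterwards, each
tracking iteration fits a uniform cubic B-spline segment through four
sliding control points and appends the segment (valid between the middle
two control points) to the fiber.  The next control points are found by
stepping along the dODF local maximum best aligned with the incoming
direction, so noisy single-voxel orientations perturb the path less than
they would a piecewise-linear streamline.

Coordinates: control points and fiber samples live in *world-scaled voxel
space* (voxel index times voxel size, mm), which makes step lengths and
turning angles metric even for anisotropic voxels; finished fibers are
converted back to continuous voxel coordinates.  dODF and FA lookups use
the nearest voxel (no interpolation); only the spline geometry is
continuous.

Termination: a fiber stops when it reaches a voxel with FA at or below the
threshold, turns by at least ``theta_max`` between the chords of
consecutive iterations, leaves the volume, finds no acceptably aligned
dODF maximum, or hits the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dodf import ODFField
from .exceptions import ValidationError
from .io_formats import Fiber
from .tensor_model import FAVolume

#: uniform cubic B-spline basis matrix (rows weight u^3, u^2, u, 1)
BSPLINE_BASIS = (
    np.array(
        [
            [-1.0, 3.0, -3.0, 1.0],
            [3.0, -6.0, 3.0, 0.0],
            [-3.0, 0.0, 3.0, 0.0],
            [1.0, 4.0, 1.0, 0.0],
        ]
    )
    / 6.0
)

TERMINATION_REASONS = ("angle", "low_fa", "out_of_bounds", "no_direction", "max_iters")


@dataclass
class TrackingParams:
    """Tunable tracking parameters.

    ``h`` is the step length in millimetres (converted through the voxel
    size internally), ``theta_max`` the maximum turning angle between
    consecutive iteration chords in degrees, ``fa_min`` the FA stopping
    threshold, ``nu`` the spline sampling increment, and
    ``smoothing_stride`` the subsampling stride of the final smoothing
    pass.
    """

    h: float = 1.0
    theta_max: float = 60.0
    fa_min: float = 0.15
    nu: float = 0.01
    smoothing_stride: int = 20
    max_iters: int = 2000
    min_length: float = 10.0   # mm

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValidationError("step length h must be > 0")
        if not 0 < self.theta_max < 180:
            raise ValidationError("theta_max must be in (0, 180) degrees")
        if not 0 <= self.fa_min < 1:
            raise ValidationError("fa_min must be in [0, 1)")
        if not 0 < self.nu <= 0.5:
            raise ValidationError("nu must be in (0, 0.5]")
        if self.smoothing_stride < 1:
            raise ValidationError("smoothing stride must be >= 1")


@dataclass
class TrackerState:
    """Sliding state of one propagation direction."""

    control: np.ndarray                    # (4, 3) p0..p3, mm space
    points: list = field(default_factory=list)  # accumulated samples, mm
    iteration: int = 1
    termination: str | None = None

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        if self.control.shape != (4, 3):
            raise ValidationError("require at least four control points")


def bspline_segment(p0, p1, p2, p3, nu: float) -> np.ndarray:
    """Sample one uniform cubic B-spline segment.

    Evaluates ``s(u) = [u^3, u^2, u, 1] B [p0; p1; p2; p3]`` at
    ``u in {0, nu, 2 nu, ..., 1}`` (``floor(1/nu) + 1`` samples).  The
    segment interpolates the region between the middle two control points:
    ``s(0) = (p0 + 4 p1 + p2) / 6`` and ``s(1) = (p1 + 4 p2 + p3) / 6``.
    """
    if not 0 < nu <= 0.5:
        raise ValidationError("nu must be in (0, 0.5]")
    try:
        ctrl = np.array([p0, p1, p2, p3], dtype=float)
    except ValueError as exc:
        raise ValidationError("require at least four control points") from exc
    if ctrl.shape != (4, 3):
        raise ValidationError("require at least four control points")
    n = int(np.floor(1.0 / nu)) + 1
    u = np.arange(n) * nu
    U = np.column_stack([u**3, u**2, u, np.ones_like(u)])
    return U @ BSPLINE_BASIS @ ctrl


class _Field:
    """Nearest-voxel lookup helper shared by the trackers (mm <-> voxel)."""

    def __init__(self, odf: ODFField, fa: FAVolume, voxel_size) -> None:
        self.odf = odf
        self.fa = fa
        self.voxel_size = np.asarray(voxel_size, dtype=float)
        self.shape = np.asarray(fa.spatial_shape)

    def to_mm(self, vox_pts: np.ndarray) -> np.ndarray:
        return np.asarray(vox_pts, float) * self.voxel_size

    def to_vox(self, mm_pts: np.ndarray) -> np.ndarray:
        return np.asarray(mm_pts, float) / self.voxel_size

    def nearest_voxel(self, mm_pt) -> np.ndarray | None:
        # round half-up for a deterministic tie rule
        ijk = np.floor(self.to_vox(mm_pt) + 0.5).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.shape):
            return None
        return ijk

    def fa_at(self, mm_pt) -> float | None:
        ijk = self.nearest_voxel(mm_pt)
        if ijk is None:
            return None
        v = self.fa.data[tuple(ijk)]
        return float(v) if np.isfinite(v) else 0.0

    def maxima_at(self, mm_pt) -> np.ndarray | None:
        ijk = self.nearest_voxel(mm_pt)
        if ijk is None:
            return None
        return self.odf.maxima_at(ijk)


def step_direction(odf: ODFField, point_mm, incoming_dir, voxel_size=1.0,
                   fa: FAVolume | None = None) -> np.ndarray | None:
    """Best-aligned signed dODF maximum at the voxel nearest ``point_mm``.

    Maxima are axial; both signs of every axis are considered and the one
    with the largest dot product with ``incoming_dir`` wins (an exactly
    perpendicular axis resolves to its + orientation, and the turning-angle
    stop rule then terminates the fiber).  Returns None when the point is
    outside the volume or the maxima set is empty.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    vox = np.asarray(point_mm, float) / voxel_size
    ijk = np.floor(vox + 0.5).astype(int)
    shape = np.asarray(odf.spatial_shape)
    if np.any(ijk < 0) or np.any(ijk >= shape):
        return None
    M = odf.maxima_at(ijk)
    if M is None or len(M) == 0:
        return None
    incoming = np.asarray(incoming_dir, float)
    dots = M @ incoming
    best = int(np.argmax(np.abs(dots)))
    return M[best] if dots[best] >= 0 else -M[best]


def _initial_direction(field: _Field, seed_mm) -> np.ndarray | None:
    """Largest-amplitude dODF maximum at the seed (axial; sign arbitrary)."""
    M = field.maxima_at(seed_mm)
    if M is None or len(M) == 0:
        return None
    return M[0]


def seed_initialize(
    seed_vox, odf: ODFField, fa: FAVolume, params: TrackingParams,
    voxel_size=1.0, initial_dir: np.ndarray | None = None,
) -> TrackerState | None:
    """Place the four initial control points around a seed.

    ``p1`` is the seed; ``p2 = p1 + h Q1`` with ``Q1`` the chosen dODF
    maximum at the seed (the global maximum by default); ``p0`` is the
    mirror step backwards; ``p3 = p2 + h Q2`` with ``Q2`` the maximum at
    ``p2`` best aligned with ``Q1``.  Returns None for seeds with no
    direction information or subthreshold FA.
    """
    field = _Field(odf, fa, voxel_size)
    p1 = field.to_mm(np.asarray(seed_vox, float))
    fa_here = field.fa_at(p1)
    if fa_here is None or fa_here <= params.fa_min:
        return None
    q1 = _initial_direction(field, p1) if initial_dir is None else np.asarray(initial_dir, float)
    if q1 is None:
        return None
    q1 = q1 / np.linalg.norm(q1)
    p2 = p1 + params.h * q1
    p0 = p1 - params.h * q1
    q2 = step_direction(odf, p2, q1, field.voxel_size)
    if q2 is None:
        q2 = q1  # continue straight when p2 carries no information yet
    p3 = p2 + params.h * q2
    return TrackerState(np.array([p0, p1, p2, p3]))


def advance(
    state: TrackerState, odf: ODFField, fa: FAVolume, params: TrackingParams,
    voxel_size=1.0,
) -> TrackerState:
    """One tracking iteration: sample the spline, slide the control points.

    Appends the segment samples to the fiber, then sets
    ``p0 <- old p1``, ``p1 <- segment end point``, ``p2 <- p1 + h Q1``,
    ``p3 <- p2 + h Q2`` with Q1/Q2 from :func:`step_direction`.  Sets
    ``state.termination`` instead of sliding when a stop rule fires.
    """
    if state.termination is not None:
        return state
    field = _Field(odf, fa, voxel_size)
    p0, p1, p2, p3 = state.control
    samples = bspline_segment(p0, p1, p2, p3, params.nu)
    if state.points and np.allclose(state.points[-1], samples[0]):
        samples = samples[1:]
    state.points.extend(samples)

    new_p1 = np.asarray(state.points[-1], float)
    new_p0 = p1
    fa_here = field.fa_at(new_p1)
    if fa_here is None:
        state.termination = "out_of_bounds"
        return state
    if fa_here <= params.fa_min:
        state.termination = "low_fa"
        return state

    prev_chord = p2 - p1
    prev_dir = prev_chord / np.linalg.norm(prev_chord)
    q1 = step_direction(odf, new_p1, prev_dir, field.voxel_size)
    if q1 is None:
        state.termination = "no_direction"
        return state
    new_p2 = new_p1 + params.h * q1

    cosang = np.clip(
        prev_dir @ (new_p2 - new_p1) / np.linalg.norm(new_p2 - new_p1), -1.0, 1.0
    )
    if np.degrees(np.arccos(cosang)) >= params.theta_max:
        state.termination = "angle"
        return state

    q2 = step_direction(odf, new_p2, q1, field.voxel_size)
    if q2 is None:
        q2 = q1
    new_p3 = new_p2 + params.h * q2

    state.control = np.array([new_p0, new_p1, new_p2, new_p3])
    state.iteration += 1
    if state.iteration > params.max_iters:
        state.termination = "max_iters"
    return state


def _run_direction(seed_vox, odf, fa, params, voxel_size, initial_dir):
    state = seed_initialize(
        seed_vox, odf, fa, params, voxel_size, initial_dir=initial_dir
    )
    if state is None:
        return None
    while state.termination is None:
        advance(state, odf, fa, params, voxel_size)
    return state


def track_from_seed(
    seed_vox, odf: ODFField, fa: FAVolume, params: TrackingParams, voxel_size=1.0,
) -> Fiber | None:
    """Track bidirectionally from one seed voxel and smooth the result.

    Propagates along the seed's principal dODF maximum and its opposite,
    concatenates the reversed backward half with the forward half, applies
    :func:`final_smooth` and discards fibers shorter than
    ``params.min_length`` (mm).  Tracking has no randomness: identical
    inputs give identical fibers.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    field = _Field(odf, fa, voxel_size)
    seed_mm = field.to_mm(np.asarray(seed_vox, float))
    q1 = _initial_direction(field, seed_mm)
    if q1 is None:
        return None
    fwd = _run_direction(seed_vox, odf, fa, params, voxel_size, q1)
    bwd = _run_direction(seed_vox, odf, fa, params, voxel_size, -q1)

    pieces = []
    if bwd is not None and bwd.points:
        pieces.append(np.asarray(bwd.points)[::-1])
    pieces.append(seed_mm[None, :])
    if fwd is not None and fwd.points:
        pieces.append(np.asarray(fwd.points))
    pts_mm = np.vstack(pieces)
    if len(pts_mm) < 2:
        return None

    length = np.linalg.norm(np.diff(pts_mm, axis=0), axis=1).sum()
    if length < params.min_length:
        return None
    fiber = Fiber.from_points(pts_mm / voxel_size)
    reasons = {
        "forward": fwd.termination if fwd is not None else "rejected",
        "backward": bwd.termination if bwd is not None else "rejected",
    }
    smoothed = final_smooth(fiber, params)
    smoothed.flags.add(f"stop:{reasons['forward']}/{reasons['backward']}")
    return smoothed


def final_smooth(fiber: Fiber, params: TrackingParams) -> Fiber:
    """Post-hoc whole-fiber smoothing with cubic B-splines.

    The iterative segments are not continuous across iterations, so the
    finished trajectory is subsampled at every ``smoothing_stride``-th point
    (first and last always kept) and re-expressed as a chain of cubic
    B-spline segments over consecutive 4-point windows, with duplicated
    phantom points at the two ends.  Fibers too short to supply a window
    are returned unsmoothed and flagged.
    """
    pts = fiber.points
    stride = params.smoothing_stride
    idx = list(range(0, len(pts), stride))
    if idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    ctrl = pts[idx]
    if len(ctrl) < 2:
        out = Fiber(pts.copy())
        out.flags.add("unsmoothed")
        return out
    padded = np.vstack([ctrl[0], ctrl, ctrl[-1]])
    nu = 1.0 / max(stride, 2)
    segments = []
    for k in range(len(padded) - 3):
        seg = bspline_segment(*padded[k : k + 4], nu=nu)
        if segments:
            seg = seg[1:]
        segments.append(seg)
    return Fiber.from_points(np.vstack(segments), scalars={}, )
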