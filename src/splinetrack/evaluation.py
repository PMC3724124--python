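"""Ground-truth scoring of tractograms on phantoms with known geometry.

Two complementary strategies:

* a spatial metric: candidate and truth fibers are resampled to ``s``
  points with a chord-length-parameterized interpolating cubic spline and
  compared by the mean pointwise Euclidean distance (minimized over the
  two traversal orders, so fiber orientation does not matter);
* connectivity: a fiber connects an ROI pair iff its two *endpoints* land
  in the two masks (one each).  A pass-through mode relaxes the endpoint
  rule to intersection anywhere along the fiber.

Distances are reported in millimetres (voxel coordinates scaled by the
voxel size) so results are comparable across grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import ValidationError
from .io_formats import Fiber, Tractogram
from .tract_ops import nearest_voxels, select_by_rois


@dataclass
class BundleScore:
    """Per-bundle comparison of candidate fibers against one truth fiber."""

    bundle_id: int
    mean_l2: float            # mm; NaN when no candidate connects
    min_l2: float             # mm; NaN when no candidate connects
    n_candidates: int
    connected: bool

    def __post_init__(self) -> None:
        if self.connected != (self.n_candidates > 0):
            raise ValidationError("connectivity flag inconsistent with count")


def resample_interpolating(fiber: Fiber, s: int = 1000) -> Fiber:
    """Resample a fiber to ``s`` points with an interpolating cubic spline.

    The spline passes through every original point (natural end
    conditions), is parameterized by cumulative chord length and evaluated
    at ``s`` equally spaced parameter values; the original endpoints are
    preserved exactly.  Consecutive duplicate points are collapsed first.
    """
    pts = np.asarray(fiber.points, float)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 2:
        raise ValidationError("cannot resample a degenerate fiber")
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    t = np.linspace(0.0, chord[-1], s)
    if len(pts) == 2:  # a straight segment: interpolate linearly
        frac = (t / chord[-1])[:, None]
        out = pts[0] + frac * (pts[1] - pts[0])
    else:
        spline = CubicSpline(chord, pts, bc_type="natural")
        out = spline(t)
    out[0] = pts[0]
    out[-1] = pts[-1]
    return Fiber(out)


def fiber_l2_distance(f1: Fiber, f2: Fiber, s: int = 1000,
                      voxel_size=1.0) -> float:
    """Mean pointwise distance between two fibers after resampling to ``s``
    corresponding points, minimized over the two traversal orders.

    Symmetric in its arguments and zero for identical curves regardless of
    orientation.  ``voxel_size`` converts to mm.
    """
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    a = resample_interpolating(f1, s).points * vs
    b = resample_interpolating(f2, s).points * vs
    fwd = np.linalg.norm(a - b, axis=1).mean()
    rev = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(fwd, rev))


def connectivity_score(tractogram: Tractogram, roi_pairs,
                       mode: str = "endpoint"):
    """Count fibers connecting each ROI pair.

    In the default endpoint mode a fiber connects (A, B) iff one endpoint's
    nearest voxel lies in A and the other's in B.  ``mode="passthrough"``
    instead requires intersection with both masks anywhere along the
    fiber.  Returns ``(counts, n_connected)``.
    """
    if mode not in ("endpoint", "passthrough"):
        raise ValidationError("mode must be 'endpoint' or 'passthrough'")
    counts = []
    for roi_a, roi_b in roi_pairs:
        if np.any(roi_a & roi_b):
            warnings.warn("ROI pair members overlap", stacklevel=2)
        n = 0
        for fiber in tractogram:
            if mode == "endpoint":
                ends = nearest_voxels(fiber.points[[0, -1]])
                shape = np.asarray(roi_a.shape)
                ok = np.all((ends >= 0) & (ends < shape), axis=1)
                in_a = [bool(roi_a[tuple(e)]) if o else False for e, o in zip(ends, ok)]
                in_b = [bool(roi_b[tuple(e)]) if o else False for e, o in zip(ends, ok)]
                if (in_a[0] and in_b[1]) or (in_a[1] and in_b[0]):
                    n += 1
            else:
                ijk = nearest_voxels(fiber.points)
                shape = np.asarray(roi_a.shape)
                ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
                ijk = ijk[ok]
                if roi_a[tuple(ijk.T)].any() and roi_b[tuple(ijk.T)].any():
                    n += 1
        counts.append(n)
    n_connected = int(sum(c >= 1 for c in counts))
    return counts, n_connected


def score_against_truth(
    candidate: Tractogram,
    truth_fibers,
    roi_pairs,
    s: int = 1000,
    selection_mode: str = "passthrough",
):
    """Score a tractogram bundle-by-bundle against ground-truth fibers.

    For each truth fiber, candidates are selected by its ROI pair
    (pass-through AND by default, endpoint rule optional) and the mean and
    min spatial metric over the selected candidates is computed.  Bundles
    with no candidate are reported non-connected with NaN distance and
    excluded from the grand mean.

    Returns ``(scores, grand_mean)`` with distances in mm.
    """
    if roi_pairs is None or len(roi_pairs) != len(truth_fibers):
        raise ValidationError("need one ROI pair per truth fiber")
    vs = candidate.voxel_size
    scores = []
    means = []
    for k, (truth, pair) in enumerate(zip(truth_fibers, roi_pairs)):
        if selection_mode == "passthrough":
            selected = select_by_rois(candidate, list(pair), mode="AND").fibers
        else:
            sub, _ = _select_endpoint(candidate, pair)
            selected = sub
        if not selected:
            scores.append(BundleScore(k, float("nan"), float("nan"), 0, False))
            continue
        dists = [fiber_l2_distance(f, truth, s, vs) for f in selected]
        scores.append(
            BundleScore(k, float(np.mean(dists)), float(np.min(dists)),
                        len(selected), True)
        )
        means.append(np.mean(dists))
    grand = float(np.mean(means)) if means else float("nan")
    return scores, grand


def _select_endpoint(tractogram: Tractogram, pair):
    keep = []
    roi_a, roi_b = pair
    shape = np.asarray(roi_a.shape)
    for fiber in tractogram:
        ends = nearest_voxels(fiber.points[[0, -1]])
        ok = np.all((ends >= 0) & (ends < shape), axis=1)
        in_a = [bool(roi_a[tuple(e)]) if o else False for e, o in zip(ends, ok)]
        in_b = [bool(roi_b[tuple(e)]) if o else False for e, o in zip(ends, ok)]
        if (in_a[0] and in_b[1]) or (in_a[1] and in_b[0]):
            keep.append(fiber)
    return keep, len(keep)


def step_length_sweep(
    h_values,
    track_fn,
    truth_fibers,
    roi_pairs,
    s: int = 1000,
) -> pd.DataFrame:
    """Grand-mean spatial metric as a function of the step length h.

    ``track_fn(h)`` must return the candidate :class:`Tractogram` tracked
    with step length ``h`` (all other parameters held fixed).  Returns a
    table with one row per h.
    """
    if len(list(h_values)) < 1:
        raise ValidationError("need at least one step length")
    rows = []
    for h in h_values:
        tractogram = track_fn(h)
        scores, grand = score_against_truth(tractogram, truth_fibers, roi_pairs, s)
        rows.append(
            {
                "h_mm": float(h),
                "grand_mean_l2_mm": grand,
                "n_connected": sum(sc.connected for sc in scores),
                "n_fibers": len(tractogram),
            }
        )
    return pd.DataFrame(rows)
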