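"""ROI-based tract selection and FA summaries.

Three complementary FA summaries are provided for a selected bundle:

* tract-mean: FA sampled at the nearest voxel of every fiber point,
  averaged over all points of all fibers (point-weighted);
* voxel-mean: every voxel visited by at least one fiber counted once,
  FA averaged over the visited-voxel set (tract density ignored);
* along-tract profile: every fiber reoriented to a common start,
  arc-length normalized, resampled to a fixed number of positions and
  summarized position by position, which exposes local FA structure
  (e.g. crossing-induced dips) that a single mean hides.

Point-to-voxel mapping rounds continuous voxel coordinates to the nearest
voxel center, with half-integer ties rounded toward +inf for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io_formats import Fiber, Tractogram
from .tensor_model import FAVolume


def nearest_voxels(points: np.ndarray) -> np.ndarray:
    """Round continuous voxel coordinates to integer voxel indices
    (half-up tie rule)."""
    return np.floor(np.asarray(points, float) + 0.5).astype(int)


def _fa_at_points(points: np.ndarray, fa: FAVolume) -> np.ndarray:
    ijk = nearest_voxels(points)
    shape = np.asarray(fa.spatial_shape)
    ijk = np.clip(ijk, 0, shape - 1)
    vals = fa.data[tuple(ijk.T)]
    return np.where(np.isfinite(vals), vals, 0.0)


def _fiber_hits_roi(fiber: Fiber, roi: np.ndarray) -> bool:
    ijk = nearest_voxels(fiber.points)
    shape = np.asarray(roi.shape)
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not np.any(ok):
        return False
    return bool(roi[tuple(ijk[ok].T)].any())


def select_by_rois(
    tractogram: Tractogram, roi_list, mode: str = "AND"
) -> Tractogram:
    """Keep fibers intersecting every ROI (AND) or any ROI (OR).

    A fiber intersects an ROI when at least one point's nearest voxel is
    foreground.  This is the classical two-ROI tract definition: the named
    bundle is the set of fibers passing through both delineations.
    """
    if mode not in ("AND", "OR"):
        raise ValidationError(f"mode must be AND or OR, got {mode!r}")
    for i, roi in enumerate(roi_list):
        if not np.any(roi):
            raise ValidationError(f"ROI #{i} is empty")
    keep = []
    for fiber in tractogram:
        hits = [_fiber_hits_roi(fiber, roi) for roi in roi_list]
        if (mode == "AND" and all(hits)) or (mode == "OR" and any(hits)):
            keep.append(fiber)
    return Tractogram(keep, tractogram.affine, tractogram.voxel_size,
                      tractogram.space_tag)


def truncate_at_roi(fiber: Fiber, roi: np.ndarray, keep_side: str = "after") -> Fiber:
    """Cut a fiber at its first point inside an ROI.

    Scanning starts from the designated end (``keep_side="after"`` scans
    from the start, ``"before"`` from the end); the cut point itself is
    kept.  A fiber that never enters the ROI is returned unchanged with a
    ``no_roi_intersection`` flag.
    """
    if keep_side not in ("after", "before"):
        raise ValidationError("keep_side must be 'after' or 'before'")
    ijk = nearest_voxels(fiber.points)
    shape = np.asarray(roi.shape)
    ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
    inside = np.zeros(len(fiber), dtype=bool)
    inside[ok] = roi[tuple(ijk[ok].T)]
    if not np.any(inside):
        out = Fiber(fiber.points.copy(), dict(fiber.scalars), set(fiber.flags))
        out.flags.add("no_roi_intersection")
        return out
    if keep_side == "after":
        cut = int(np.argmax(inside))
        sl = slice(cut, None)
    else:
        cut = len(fiber) - 1 - int(np.argmax(inside[::-1]))
        sl = slice(None, cut + 1)
    pts = fiber.points[sl]
    if len(pts) < 2:  # degenerate cut at an endpoint: keep the endpoint pair
        sl = slice(max(cut - 1, 0), cut + 1) if keep_side == "before" else \
            slice(cut, cut + 2)
        pts = fiber.points[sl]
    return Fiber(pts.copy(), {k: v[sl].copy() for k, v in fiber.scalars.items()},
                 set(fiber.flags))


def tract_mean_fa(tractogram: Tractogram, fa: FAVolume):
    """Point-weighted tract FA: grand mean over all fiber points.

    Returns ``(grand_mean, per_fiber_means)``.  Fibers with more points
    weigh more; see :func:`voxel_mean_fa` for the density-free variant.
    """
    if len(tractogram) == 0:
        raise ValidationError("tract mean undefined for an empty tractogram")
    all_vals = []
    per_fiber = []
    for fiber in tractogram:
        vals = _fa_at_points(fiber.points, fa)
        all_vals.append(vals)
        per_fiber.append(float(vals.mean()))
    grand = float(np.concatenate(all_vals).mean())
    return grand, np.asarray(per_fiber)


def voxel_mean_fa(tractogram: Tractogram, fa: FAVolume) -> float:
    """FA averaged over the set of voxels visited by at least one fiber;
    each voxel counts once regardless of how many fibers (or points)
    touch it."""
    if len(tractogram) == 0:
        raise ValidationError("voxel mean undefined for an empty tractogram")
    shape = np.asarray(fa.spatial_shape)
    visited = set()
    for fiber in tractogram:
        ijk = nearest_voxels(fiber.points)
        ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
        visited.update(map(tuple, ijk[ok]))
    idx = np.array(sorted(visited))
    vals = fa.data[tuple(idx.T)]
    vals = np.where(np.isfinite(vals), vals, 0.0)
    return float(vals.mean())


@dataclass
class AlongTractProfile:
    """FA summarized along normalized tract length."""

    positions: np.ndarray     # (n,) fractions in [0, 1], strictly increasing
    mean_fa: np.ndarray       # (n,)
    sd_fa: np.ndarray         # (n,)
    per_fiber: np.ndarray     # (n_fibers, n)

    @property
    def n_fibers(self) -> int:
        return len(self.per_fiber)


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Arc-length parameterize a polyline and resample it at ``n`` equal
    fractions by linear interpolation."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    s /= s[-1]
    si = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(si, s, pts[:, d]) for d in range(3)])


def _orient_fibers(fibers: list[Fiber], anchor: np.ndarray | None) -> list[np.ndarray]:
    """Point all fibers the same way along the bundle.

    With an anchor (e.g. an ROI centroid) each fiber starts at the endpoint
    nearer the anchor.  Otherwise endpoints are projected on their first
    principal axis and each fiber starts at its lower-projection end.
    """
    pts = [f.points for f in fibers]
    if anchor is not None:
        anchor = np.asarray(anchor, float)
        return [
            p if np.linalg.norm(p[0] - anchor) <= np.linalg.norm(p[-1] - anchor)
            else p[::-1]
            for p in pts
        ]
    ends = np.vstack([[p[0], p[-1]] for p in pts])
    center = ends.mean(axis=0)
    u, s, vt = np.linalg.svd(ends - center, full_matrices=False)
    axis = vt[0]
    out = []
    for p in pts:
        if (p[0] - center) @ axis <= (p[-1] - center) @ axis:
            out.append(p)
        else:
            out.append(p[::-1])
    return out


def along_tract_profile(
    tractogram: Tractogram,
    fa: FAVolume,
    n_points: int = 100,
    anchor: np.ndarray | None = None,
) -> AlongTractProfile:
    """Along-tract FA profile over normalized tract length.

    Fibers are reoriented to a common start (anchor ROI centroid, else a
    PCA endpoint rule), resampled to ``n_points`` equal arc-length
    fractions, and FA is sampled at the nearest voxel of each resampled
    point.  Fibers are weighted equally in the positionwise mean so long
    fibers do not dominate.
    """
    if len(tractogram) == 0:
        raise ValidationError("profile undefined for an empty tractogram")
    oriented = _orient_fibers(list(tractogram.fibers), anchor)
    mat = np.stack(
        [_fa_at_points(resample_polyline(p, n_points), fa) for p in oriented]
    )
    positions = np.linspace(0.0, 1.0, n_points)
    return AlongTractProfile(
        positions=positions,
        mean_fa=mat.mean(axis=0),
        sd_fa=mat.std(axis=0, ddof=0),
        per_fiber=mat,
    )
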