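"""Reference streamline trackers: Euler integration of the Frenet equation.

The curve r(s) satisfies dr/ds = t(s) and is advanced as
``r_{n+1} = r_n + h t(r_n)``.  The tangent comes either from the principal
eigenvector of the voxel's diffusion tensor (tensor mode, the classical
DTI tracker) or from the dODF local maximum best aligned with the incoming
direction (dODF mode).  Both share the spline tracker's termination rules
(turning angle, FA threshold, bounds, missing direction) so that method
comparisons isolate the propagation scheme itself.

Fixed-step Euler is used throughout; voxel-boundary (FACT-style) stepping
is deliberately not emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dodf import ODFField
from .io_formats import Fiber, Tractogram
from .spline_tracker import (
    TrackingParams,
    _Field,
    final_smooth,
    step_direction,
    track_from_seed,
)
from .tensor_model import FAVolume, TensorField, principal_direction_field


@dataclass
class DirectionProvider:
    """Unit-tangent source for streamline tracking.

    ``mode`` is ``"tensor"`` (principal eigenvector field) or ``"dodf"``
    (best-aligned dODF maximum).  Returns unit vectors or None.
    """

    mode: str
    odf: ODFField | None = None
    directions: np.ndarray | None = None    # (X, Y, Z, 3) for tensor mode

    @classmethod
    def from_tensor(cls, tensors: TensorField) -> "DirectionProvider":
        vecs, _ = principal_direction_field(tensors)
        return cls(mode="tensor", directions=vecs)

    @classmethod
    def from_odf(cls, odf: ODFField) -> "DirectionProvider":
        return cls(mode="dodf", odf=odf)

    @property
    def spatial_shape(self):
        if self.mode == "tensor":
            return self.directions.shape[:3]
        return self.odf.spatial_shape

    def initial(self, ijk) -> np.ndarray | None:
        """Direction at a voxel with no incoming orientation (axial)."""
        if self.mode == "tensor":
            v = self.directions[tuple(ijk)]
            n = np.linalg.norm(v)
            return v / n if n > 0 else None
        M = self.odf.maxima_at(ijk)
        if M is None or len(M) == 0:
            return None
        return M[0]

    def tangent(self, point_mm, incoming, voxel_size) -> np.ndarray | None:
        """Signed unit tangent at ``point_mm`` resolved against ``incoming``."""
        voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        ijk = np.floor(np.asarray(point_mm, float) / voxel_size + 0.5).astype(int)
        shape = np.asarray(self.spatial_shape)
        if np.any(ijk < 0) or np.any(ijk >= shape):
            return None
        if self.mode == "tensor":
            v = self.directions[tuple(ijk)]
            n = np.linalg.norm(v)
            if n == 0:
                return None
            v = v / n
            d = float(v @ np.asarray(incoming, float))
            if d == 0:
                return None
            return v if d > 0 else -v
        return step_direction(self.odf, point_mm, incoming, voxel_size)


def _euler_half(seed_mm, init_dir, provider, field, params):
    pts = []
    r = np.asarray(seed_mm, float)
    direction = np.asarray(init_dir, float)
    reason = None
    for _ in range(params.max_iters):
        r_new = r + params.h * direction
        fa_here = field.fa_at(r_new)
        if fa_here is None:
            reason = "out_of_bounds"
            break
        if fa_here <= params.fa_min:
            reason = "low_fa"
            break
        pts.append(r_new)
        t_new = provider.tangent(r_new, direction, field.voxel_size)
        if t_new is None:
            reason = "no_direction"
            break
        cosang = np.clip(direction @ t_new, -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) >= params.theta_max:
            reason = "angle"
            break
        r, direction = r_new, t_new
    else:
        reason = "max_iters"
    return pts, reason


def euler_track(
    seed_vox,
    provider: DirectionProvider,
    fa: FAVolume,
    params: TrackingParams,
    voxel_size=1.0,
    post_smooth: bool = False,
) -> Fiber | None:
    """Bidirectional fixed-step Euler streamline from one seed voxel.

    Step spacing is exactly ``h`` (mm); the tangent sign is resolved
    against the incoming direction, and at the seed against the provider's
    initial (axial) direction.  With ``post_smooth`` the spline tracker's
    final smoothing pass is applied afterwards (labelled in the fiber
    flags) -- by default the raw polyline is returned.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    # FA lookups only need the _Field helper, not an ODF
    field = _Field(provider.odf, fa, voxel_size) if provider.mode == "dodf" \
        else _Field(_NoOdf(), fa, voxel_size)
    seed_mm = field.to_mm(np.asarray(seed_vox, float))
    ijk = field.nearest_voxel(seed_mm)
    if ijk is None:
        return None
    fa_here = field.fa_at(seed_mm)
    if fa_here is None or fa_here <= params.fa_min:
        return None
    q1 = provider.initial(ijk)
    if q1 is None:
        return None

    fwd, _ = _euler_half(seed_mm, q1, provider, field, params)
    bwd, _ = _euler_half(seed_mm, -q1, provider, field, params)
    pts_mm = np.vstack(
        [np.asarray(bwd)[::-1] if bwd else np.zeros((0, 3)), seed_mm[None, :],
         np.asarray(fwd) if fwd else np.zeros((0, 3))]
    )
    if len(pts_mm) < 2:
        return None
    length = np.linalg.norm(np.diff(pts_mm, axis=0), axis=1).sum()
    if length < params.min_length:
        return None
    fiber = Fiber.from_points(pts_mm / voxel_size)
    if post_smooth:
        fiber = final_smooth(fiber, params)
        fiber.flags.add("post_smoothed")
    return fiber


class _NoOdf:
    """Placeholder ODF for tensor-mode tracking (never consulted)."""

    spatial_shape = None

    def maxima_at(self, ijk):  # pragma: no cover - defensive
        raise RuntimeError("tensor-mode tracking has no ODF")


def track_wholefield(
    seed_mask: np.ndarray,
    fa: FAVolume,
    params: TrackingParams,
    provider: DirectionProvider | None = None,
    odf: ODFField | None = None,
    method: str = "euler",
    voxel_size=1.0,
    affine: np.ndarray | None = None,
) -> Tractogram:
    """Track one fiber per foreground voxel of a seed mask.

    ``method`` is ``"euler"`` (requires ``provider``) or ``"spline"``
    (requires ``odf``).  Seeds sit at voxel centers; each fiber records its
    seed voxel in ``flags``.
    """
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    seeds = np.argwhere(np.asarray(seed_mask) != 0)
    if len(seeds) == 0:
        warnings.warn("empty seed mask: returning empty tractogram", stacklevel=2)
        return Tractogram([], affine, voxel_size)

    fibers = []
    for seed in seeds:
        if method == "spline":
            if odf is None:
                raise ValueError("spline tracking requires an ODF field")
            fiber = track_from_seed(seed, odf, fa, params, voxel_size)
        elif method == "euler":
            if provider is None:
                raise ValueError("euler tracking requires a direction provider")
            fiber = euler_track(seed, provider, fa, params, voxel_size)
        else:
            raise ValueError(f"unknown tracking method {method!r}")
        if fiber is not None:
            fiber.flags.add(f"seed:{tuple(int(s) for s in seed)}")
            fibers.append(fiber)
    return Tractogram(fibers, affine, voxel_size)
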