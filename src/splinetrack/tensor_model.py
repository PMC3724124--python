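"""Voxel-wise diffusion tensor estimation, FA maps and principal directions.

The single-tensor model assumes Gaussian diffusion in each voxel,
``S(g, b) = S0 * exp(-b g^T D g)``, fitted by weighted log-linear least
squares.  Fractional anisotropy follows the standard eigenvalue formula
``FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||``.

Voxels where the fit is unreliable (non-positive S0, too many clipped
measurements) are flagged invalid rather than silently zeroed; FA is NaN
there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .io_formats import DWIVolume

#: fraction of S0 used as positivity floor before taking logarithms
CLIP_FLOOR = 1e-6
#: voxels with more than this fraction of clipped measurements are invalid
MAX_CLIP_FRACTION = 0.25
#: eigenvalue gap below which the principal direction is ambiguous
DEGENERACY_TOL = 1e-12


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors (mm^2/s) with validity flags."""

    tensors: np.ndarray          # (X, Y, Z, 3, 3)
    valid: np.ndarray            # (X, Y, Z) bool
    eigenvalues: np.ndarray = field(default=None)   # (X, Y, Z, 3) descending
    eigenvectors: np.ndarray = field(default=None)  # (X, Y, Z, 3, 3) columns match

    def __post_init__(self) -> None:
        if self.eigenvalues is None:
            # eigh returns ascending; flip to descending
            vals, vecs = np.linalg.eigh(self.tensors)
            self.eigenvalues = vals[..., ::-1]
            self.eigenvectors = vecs[..., ::-1]

    @property
    def spatial_shape(self):
        return self.tensors.shape[:3]


@dataclass
class FAVolume:
    """Scalar FA in [0, 1] on the source grid; NaN where the fit was invalid."""

    data: np.ndarray
    valid: np.ndarray

    @property
    def spatial_shape(self):
        return self.data.shape

    def at_voxel(self, ijk) -> float:
        return float(self.data[tuple(ijk)])


def _design_matrix(gtab) -> np.ndarray:
    g = gtab.bvecs[gtab.dwi_mask]
    b = gtab.bvals[gtab.dwi_mask]
    X = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    return -b[:, None] * X


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """Weighted log-linear least-squares tensor fit.

    Requires at least six weighted directions spanning 3-D and one b=0
    volume.  Weights are the squared signals, the usual first-order
    correction for log-transformed noise.  Non-positive signals are clipped
    to ``CLIP_FLOOR * S0`` before the log; a voxel with more than
    ``MAX_CLIP_FRACTION`` of its measurements clipped is flagged invalid.
    """
    gtab = dwi.gradient_table
    X = _design_matrix(gtab)
    if X.shape[0] < 6 or np.linalg.matrix_rank(X) < 6:
        raise ConfigurationError(
            "tensor fit needs >= 6 weighted directions spanning 3-D; got "
            f"{X.shape[0]} directions {gtab.bvecs[gtab.dwi_mask].round(3).tolist()}"
        )

    shape = dwi.spatial_shape
    S = dwi.signal[..., gtab.dwi_mask].reshape(-1, X.shape[0])
    S0 = dwi.s0().reshape(-1)

    valid = S0 > 0
    S0_safe = np.where(valid, S0, 1.0)
    floor = CLIP_FLOOR * S0_safe[:, None]
    clipped = S < floor
    frac_clipped = clipped.mean(axis=1)
    valid &= frac_clipped <= MAX_CLIP_FRACTION

    Sc = np.maximum(S, floor)
    Y = np.log(Sc / S0_safe[:, None])

    # batched WLS: solve (X^T W X) d = X^T W y per voxel with W = diag(S^2)
    W = Sc**2
    XtW = X.T[None, :, :] * W[:, None, :]          # (V, 6, G)
    lhs = XtW @ X                                   # (V, 6, 6)
    rhs = np.einsum("vij,vj->vi", XtW, Y)           # (V, 6)
    # regularize the (rare) numerically singular voxels to keep solve batched
    bad = np.abs(np.linalg.det(lhs)) < 1e-300
    if np.any(bad):
        lhs[bad] += np.eye(6) * 1e-12
        valid &= ~bad
    d = np.linalg.solve(lhs, rhs[..., None])[..., 0]   # (V, 6)

    T = np.empty((len(d), 3, 3))
    T[:, 0, 0] = d[:, 0]
    T[:, 1, 1] = d[:, 1]
    T[:, 2, 2] = d[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = d[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = d[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = d[:, 5]
    return TensorField(T.reshape(*shape, 3, 3), valid.reshape(shape))


def fa_from_eigenvalues(l1, l2, l3) -> np.ndarray | float:
    """Fractional anisotropy from (broadcastable) eigenvalue triples.

    Negative eigenvalues are clamped to zero first; an all-zero triple has
    FA defined as 0.
    """
    lam = np.stack(np.broadcast_arrays(
        np.maximum(np.asarray(l1, float), 0.0),
        np.maximum(np.asarray(l2, float), 0.0),
        np.maximum(np.asarray(l3, float), 0.0),
    ), axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fa_volume(tensors: TensorField) -> FAVolume:
    lam = tensors.eigenvalues
    fa = fa_from_eigenvalues(lam[..., 0], lam[..., 1], lam[..., 2])
    fa = np.where(tensors.valid, fa, np.nan)
    return FAVolume(fa, tensors.valid.copy())


_CANONICAL = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


def principal_direction_field(tensors: TensorField):
    """Unit principal eigenvector per voxel, with a deterministic sign.

    Directions are axial, so the sign is fixed by requiring a nonnegative
    dot product with (1,1,1)/sqrt(3); exact ties are broken by making the
    first nonzero component positive.  Voxels with ``lambda1 ~ lambda2``
    are returned but flagged planar-degenerate.

    Returns ``(directions, degenerate)``: (X,Y,Z,3) unit vectors and a
    boolean flag volume.
    """
    lam = tensors.eigenvalues
    vec = tensors.eigenvectors[..., 0].copy()      # principal column
    norms = np.linalg.norm(vec, axis=-1, keepdims=True)
    vec /= np.where(norms > 0, norms, 1.0)

    dots = vec @ _CANONICAL
    flip = dots < 0
    tie = np.abs(dots) < 1e-12
    if np.any(tie):
        # first nonzero component positive
        v = vec[tie]
        first = np.argmax(np.abs(v) > 1e-12, axis=-1)
        signs = np.sign(v[np.arange(len(v)), first])
        flip_tie = signs < 0
        idx = np.zeros(tie.shape, dtype=bool)
        idx[tie] = flip_tie
        flip = np.where(tie, idx, flip)
    vec[flip] *= -1

    degenerate = (lam[..., 0] - lam[..., 1]) <= DEGENERACY_TOL
    return vec, degenerate
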