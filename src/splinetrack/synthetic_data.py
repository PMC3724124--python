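"""Synthetic diffusion phantoms and longitudinal FA tables.

DWI phantoms are built from Gaussian multi-tensor mixing: each voxel's
signal is ``S0 * sum_k f_k exp(-b g^T D_k g)`` with volume fractions
proportional to bundle occupancy plus an isotropic background compartment,
followed by optional Rician corruption (magnitude of a complex Gaussian).
Bundles are tubes around parametric centerlines with known ground-truth
coordinates and endpoint ROIs, which makes every tracking and evaluation
module testable without scanner data.

The longitudinal generator draws per-subject random intercepts/slopes
around a population line, the generative counterpart of the mixed-effects
model in :mod:`splinetrack.longitudinal_stats`.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial

from .exceptions import ValidationError
from .io_formats import DWIVolume, Fiber, GradientTable

# default single-fiber tensor eigenvalues (mm^2/s), a typical healthy
# white-matter profile (FA ~ 0.87)
DEFAULT_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)
# free-water-like isotropic background diffusivity (mm^2/s)
DEFAULT_BACKGROUND_ADC = 2.0e-3


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (spherical Fibonacci)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_gradient_table(n_directions: int = 64, b: float = 1500.0, n_b0: int = 1) -> GradientTable:
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# geometry helpers (all in voxel units)


def line_centerline(p0, p1, spacing: float = 0.25) -> np.ndarray:
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / spacing)), 1) + 1
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0 + t * (p1 - p0)


def arc_centerline(center, radius, deg0, deg1, z, spacing: float = 0.25) -> np.ndarray:
    center = np.asarray(center, float)
    arclen = abs(np.radians(deg1 - deg0)) * radius
    n = max(int(np.ceil(arclen / spacing)), 2) + 1
    ang = np.radians(np.linspace(deg0, deg1, n))
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang),
         np.full(n, float(z))]
    )


def _densify(polyline: np.ndarray, spacing: float) -> np.ndarray:
    pts = np.asarray(polyline, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing)), 1) + 1
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, pts[:, d]) for d in range(3)])


def _tangents(pts: np.ndarray) -> np.ndarray:
    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t


@dataclass
class BundleLayout:
    """A tubular fiber bundle: centerline polyline, tube radius and the
    eigenvalues of its (axially symmetric about the local tangent) tensor."""

    centerline: np.ndarray                  # (n, 3) voxel units
    radius: float = 2.0                     # voxels
    eigenvalues: tuple = DEFAULT_EIGENVALUES  # mm^2/s, descending

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, float)
        ev = np.asarray(self.eigenvalues, float)
        if self.radius <= 0:
            raise ValidationError("bundle radius must be positive")
        if np.any(ev <= 0) or np.any(np.diff(ev) > 0):
            raise ValidationError("eigenvalues must be positive and sorted descending")


@dataclass
class PhantomSpec:
    """Full description of a synthetic DWI phantom."""

    shape: tuple = (64, 64, 3)
    voxel_size: tuple = (3.0, 3.0, 3.0)     # mm
    bundles: list = field(default_factory=list)
    background_adc: float = DEFAULT_BACKGROUND_ADC
    gradient_table: GradientTable | None = None
    s0: float = 100.0
    noise_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if any(s <= 0 for s in self.shape):
            raise ValidationError("shape must be positive")
        if self.gradient_table is None:
            self.gradient_table = make_gradient_table()


# 27 sub-voxel sample offsets for partial-volume estimation
_SUBOFF = np.array(
    [[dx, dy, dz] for dx in (-1 / 3, 0, 1 / 3)
     for dy in (-1 / 3, 0, 1 / 3) for dz in (-1 / 3, 0, 1 / 3)]
)


def _bundle_occupancy(bundle: BundleLayout, shape) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy fraction per voxel (27-point subsampling of the tube
    indicator) and the unit tangent at each occupied voxel center."""
    dense = _densify(bundle.centerline, 0.1)
    tang = _tangents(dense)
    tree = scipy.spatial.cKDTree(dense)

    lo = np.maximum(np.floor(dense.min(axis=0) - bundle.radius - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(dense.max(axis=0) + bundle.radius + 1).astype(int) + 1,
        np.asarray(shape),
    )
    if np.any(lo >= hi):
        return np.zeros(shape), np.zeros(shape + (3,))
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    centers = np.stack(grids, axis=-1).reshape(-1, 3).astype(float)

    sub = centers[:, None, :] + _SUBOFF[None, :, :]
    d, _ = tree.query(sub.reshape(-1, 3), workers=-1)
    inside = (d.reshape(len(centers), 27) <= bundle.radius).mean(axis=1)

    occ = np.zeros(shape)
    tan = np.zeros(shape + (3,))
    occupied = inside > 0
    if np.any(occupied):
        _, nearest = tree.query(centers[occupied], workers=-1)
        sl = tuple(centers[occupied].astype(int).T)
        occ[sl] = inside[occupied]
        tan[sl] = tang[nearest]
    return occ, tan


def _tensor_attenuation(dirs: np.ndarray, eigenvalues, bvals, bvecs) -> np.ndarray:
    """exp(-b g^T D g) for axially symmetric tensors with principal axis
    ``dirs`` (n, 3); returns (n, G)."""
    l1, l2, l3 = eigenvalues
    lperp = 0.5 * (l2 + l3)  # axial symmetry about the tangent
    dot = dirs @ bvecs.T                     # (n, G)
    adc = lperp + (l1 - lperp) * dot**2
    return np.exp(-bvals[None, :] * adc)


def _roi_sphere(center, radius, shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack(grids, axis=-1).astype(float)
    return np.linalg.norm(pts - np.asarray(center, float), axis=-1) <= radius


def simulate_signal(spec: PhantomSpec):
    """Render a phantom to a DWI volume with ground truth.

    Returns ``(dwi, truth_fibers, roi_pairs)`` where ``truth_fibers`` are
    the bundle centerlines resampled at <= 0.5 voxel spacing and
    ``roi_pairs`` holds one (start, end) pair of spherical endpoint masks
    per bundle (radius equal to the bundle radius).
    """
    gtab = spec.gradient_table
    shape = tuple(spec.shape)
    G = len(gtab)
    bvals = gtab.bvals
    bvecs = gtab.bvecs

    occs, tans = [], []
    for bundle in spec.bundles:
        occ, tan = _bundle_occupancy(bundle, shape)
        occs.append(occ)
        tans.append(tan)

    total = np.sum(occs, axis=0) if occs else np.zeros(shape)
    over = total > 1.0
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} voxel(s) with overlapping bundles; "
            "fractions renormalized to sum 1",
            stacklevel=2,
        )
        scale = np.where(over, total, 1.0)
        occs = [occ / scale for occ in occs]
        total = np.sum(occs, axis=0)

    att = np.zeros(shape + (G,))
    for bundle, occ, tan in zip(spec.bundles, occs, tans):
        occupied = occ > 0
        if not np.any(occupied):
            continue
        E = _tensor_attenuation(tan[occupied], bundle.eigenvalues, bvals, bvecs)
        att[occupied] += occ[occupied, None] * E
    # background compartment
    iso = np.exp(-bvals * spec.background_adc)
    att += (1.0 - total)[..., None] * iso[None, None, None, :]

    signal = spec.s0 * att
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        n1 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    affine = np.diag(list(spec.voxel_size) + [1.0])
    dwi = DWIVolume(signal, affine, gtab, np.asarray(spec.voxel_size, float))

    truth = [
        Fiber(_densify(b.centerline, 0.5)) for b in spec.bundles
    ]
    roi_pairs = [
        (
            _roi_sphere(b.centerline[0], b.radius, shape),
            _roi_sphere(b.centerline[-1], b.radius, shape),
        )
        for b in spec.bundles
    ]
    return dwi, truth, roi_pairs


def make_crossing_phantom(
    angle_deg: float,
    snr: float = np.inf,
    n_directions: int = 64,
    b: float = 1500.0,
    shape=(21, 21, 5),
    radius: float = 2.5,
    seed: int = 0,
):
    """Two straight equal-fraction bundles crossing at ``angle_deg`` in the
    central region of a small slab.

    Directions are axial, so angles above 90 degrees are normalized to
    their supplement; ``angle_deg == 0`` degenerates to a single
    population.  ``snr`` is S0 over the Rician sigma (``inf`` = noiseless).

    Returns ``(dwi, truth_directions, crossing_mask)`` where
    ``truth_directions`` holds the one or two true unit fiber axes and
    ``crossing_mask`` marks voxels containing both populations.
    """
    if not 0 <= angle_deg <= 180:
        raise ValidationError("angle must be in [0, 180] degrees")
    if n_directions < 6:
        raise ValidationError("need at least 6 directions")
    if angle_deg > 90:
        angle_deg = 180.0 - angle_deg

    center = (np.asarray(shape, float) - 1) / 2.0
    half = np.radians(angle_deg) / 2.0
    u1 = np.array([np.cos(half), np.sin(half), 0.0])
    u2 = np.array([np.cos(half), -np.sin(half), 0.0])
    ext = float(max(shape)) * 1.5

    def _line_bundle(u):
        return BundleLayout(
            line_centerline(center - ext * u, center + ext * u), radius=radius
        )

    single = angle_deg == 0
    bundles = [_line_bundle(u1)] if single else [_line_bundle(u1), _line_bundle(u2)]
    gtab = make_gradient_table(n_directions, b)
    sigma = 0.0 if np.isinf(snr) else 100.0 / snr
    spec = PhantomSpec(
        shape=tuple(shape), voxel_size=(3.0, 3.0, 3.0), bundles=bundles,
        gradient_table=gtab, s0=100.0, noise_sigma=sigma, rng_seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected bundle overlap in the core
        dwi, _, _ = simulate_signal(spec)

    occ1, _ = _bundle_occupancy(bundles[0], tuple(shape))
    occ2 = occ1 if single else _bundle_occupancy(bundles[1], tuple(shape))[0]
    crossing = (occ1 > 0.45) & (occ2 > 0.45) if not single else occ1 > 0.9
    truth = np.array([u1]) if single else np.array([u1, u2])
    return dwi, truth, crossing


def fibercup_like_bundles() -> list[BundleLayout]:
    """Seven-bundle slab layout echoing the acrylic-fiber phantom's
    topology: straight 90-degree crossing pair, U-fiber, diagonal,
    tangentially kissing pair, and a broad arc."""
    z = 1.0
    r = 2.0
    return [
        # 1: long horizontal straight bundle
        BundleLayout(line_centerline((4, 52, z), (60, 52, z)), radius=r),
        # 2: vertical bundle crossing bundle 1 at 90 degrees
        BundleLayout(line_centerline((46, 38, z), (46, 62, z)), radius=r),
        # 3: U-fiber (half-circle opening upward)
        BundleLayout(arc_centerline((17, 16, z), 10.0, 180.0, 360.0, z), radius=r),
        # 4: diagonal straight bundle
        BundleLayout(line_centerline((34, 4, z), (54, 19, z)), radius=r),
        # 5/6: kissing pair, touching tangentially near (18, 32)
        BundleLayout(
            arc_centerline((18, 47.5, z), 15.0, 234.0, 306.0, z), radius=r
        ),
        BundleLayout(
            arc_centerline((18, 16.5, z), 15.0, 54.0, 126.0, z), radius=r
        ),
        # 7: broad arc on the right
        BundleLayout(arc_centerline((48, 8, z), 20.0, 50.0, 130.0, z), radius=r),
    ]


def make_fibercup_like(
    noise_sigma: float = 0.0,
    n_directions: int = 64,
    b: float = 1500.0,
    seed: int = 0,
    shape=(64, 64, 3),
):
    """A 64x64x3 synthetic slab with seven bundles and endpoint ROI pairs.

    Returns ``(dwi, truth_fibers, roi_pairs)``; each ground-truth fiber
    starts and ends inside its own ROI pair.  The endpoint ROIs are
    spheres of the bundle radius plus a 1.5-voxel margin: tracked fibers
    legitimately run a couple of voxels past the centerline ends (the tube
    caps still carry supra-threshold FA), and generous terminal ROIs --
    like the enlarged two-ROI bundle definitions used for connectivity
    scoring of the physical phantom -- keep the endpoint rule meaningful.
    Deterministic given the seed.
    """
    spec = PhantomSpec(
        shape=tuple(shape),
        voxel_size=(3.0, 3.0, 3.0),
        bundles=fibercup_like_bundles(),
        gradient_table=make_gradient_table(n_directions, b),
        s0=100.0,
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # crossing/kissing overlaps expected
        dwi, truth, _ = simulate_signal(spec)
    roi_pairs = [
        (
            _roi_sphere(bd.centerline[0], bd.radius + 1.5, tuple(shape)),
            _roi_sphere(bd.centerline[-1], bd.radius + 1.5, tuple(shape)),
        )
        for bd in spec.bundles
    ]
    return dwi, truth, roi_pairs


def simulate_longitudinal_fa(
    n_subjects: int = 8,
    waves: int = 3,
    beta0: float = 0.713,
    beta1: float = -0.00474,
    var_b0: float = 1.0e-4,
    var_b1: float = 2.5e-7,
    cov_b0_b1: float = 0.0,
    sigma2_eps: float = 1.4324e-4,
    age_range=(52.0, 66.0),
    wave_spacing: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal tract-FA table from a random-intercept/slope model.

    ``FA_ij = beta0 + beta1 * Age_ij + b0_i + b1_i * Age_ij + eps_ij`` with
    ``(b0_i, b1_i)`` zero-mean bivariate normal (independent by default)
    and iid Gaussian residuals.  Baseline ages are uniform on ``age_range``
    and increase by ``wave_spacing`` years per wave.  Defaults emulate an
    aging forceps-minor FA trajectory in elderly subjects: population line
    0.713 - 0.00474 * age, within-subject residual sd ~ 0.012, and
    subject-level dispersions chosen to be coherent under independent
    intercepts and slopes (fitted covariance matrices from real cohorts
    are near-degenerate with the intercept evaluated at age 0, so their
    raw variance components cannot be reused verbatim with
    ``cov_b0_b1=0``).

    Returns a DataFrame with columns ``subject``, ``wave``, ``age``, ``fa``.
    """
    if waves < 2:
        raise ValidationError("need at least 2 waves")
    if var_b0 < 0 or var_b1 < 0 or sigma2_eps < 0:
        raise ValidationError("variances must be >= 0")
    cov = np.array([[var_b0, cov_b0_b1], [cov_b0_b1, var_b1]])
    if np.linalg.det(cov) < -1e-15:
        raise ValidationError("random-effect covariance not positive semidefinite")

    rng = np.random.default_rng(seed)
    if var_b0 > 0 or var_b1 > 0 or cov_b0_b1 != 0:
        # svd factorization tolerates the semidefinite (zero-variance) edge
        b = rng.multivariate_normal([0.0, 0.0], cov, size=n_subjects, method="svd")
    else:
        b = np.zeros((n_subjects, 2))
    base_age = rng.uniform(age_range[0], age_range[1], size=n_subjects)

    rows = []
    for i in range(n_subjects):
        for j in range(waves):
            age = base_age[i] + j * wave_spacing
            eps = rng.normal(0.0, np.sqrt(sigma2_eps)) if sigma2_eps > 0 else 0.0
            fa = beta0 + beta1 * age + b[i, 0] + b[i, 1] * age + eps
            rows.append((i, j, age, fa))
    return pd.DataFrame(rows, columns=["subject", "wave", "age", "fa"])


def odf_field_from_directions(directions, mesh=None):
    """Build an :class:`~splinetrack.dodf.ODFField` from known directions.

    ``directions`` is an (X, Y, Z, 3) array of unit vectors (zero rows give
    voxels without orientation) or an (X, Y, Z) object array of (m, 3)
    direction sets ordered by decreasing weight.  Amplitudes are synthetic
    (1, 0.9, ... per maxima rank); the helper exists so tracking behavior
    can be probed on exactly specified orientation fields.
    """
    from .dodf import ODFField, default_mesh

    mesh = mesh or default_mesh()
    directions = np.asarray(directions, dtype=object) \
        if isinstance(directions, np.ndarray) and directions.dtype == object \
        else np.asarray(directions, dtype=float)
    if directions.dtype != object:
        if directions.ndim != 4 or directions.shape[-1] != 3:
            raise ValidationError("direction field must be (X, Y, Z, 3)")
        shape = directions.shape[:3]
        obj = np.empty(shape, dtype=object)
        for ijk in np.ndindex(shape):
            v = directions[ijk]
            n = np.linalg.norm(v)
            obj[ijk] = (v / n)[None, :] if n > 0 else np.zeros((0, 3))
        directions = obj
    shape = directions.shape
    maxima = np.empty(shape, dtype=object)
    amps = np.empty(shape, dtype=object)
    for ijk in np.ndindex(shape):
        M = np.asarray(directions[ijk], float).reshape(-1, 3)
        maxima[ijk] = M
        amps[ijk] = 1.0 - 0.1 * np.arange(len(M))
    amplitudes = np.zeros(shape + (len(mesh),))
    return ODFField(amplitudes, mesh, maxima, amps)
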