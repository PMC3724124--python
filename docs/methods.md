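# Methods

This note documents the models, numerical choices and limitations behind
`splinetrack`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and phantoms

Phantom voxels follow Gaussian multi-tensor mixing with no exchange:

    S(g, b) = S0 · [ Σ_k f_k · exp(−b gᵀ D_k g) + f_bg · exp(−b d_iso) ]

where the volume fraction `f_k` of bundle k is the fraction of 27
sub-voxel sample points (offsets −1/3, 0, +1/3 per axis) inside the
bundle's tube, `D_k` is axially symmetric about the local centerline
tangent with default eigenvalues (1.7, 0.2, 0.2)×10⁻³ mm²/s (single-fiber
FA ≈ 0.87), and the background is free-water-like isotropic diffusion with
`d_iso = 2.0×10⁻³ mm²/s`. Overlapping-bundle fractions are renormalized to
sum at most 1 (with a warning). Rician noise is applied as the magnitude
of a complex Gaussian with user-chosen σ; the default is σ = 0 because no
SNR is prescribed for the emulated acquisitions — noise level is a
configuration choice, not a claim. All generators are pure functions of
their spec and seed.

The seven-bundle slab (64×64×3 voxels, 3 mm isotropic, 64 directions at
b = 1500 s/mm², one b0) contains a straight 90° crossing pair, a U-fiber,
a diagonal bundle, a tangentially kissing arc pair and a broad arc, each
with a ground-truth centerline resampled at ≤ 0.5 voxel spacing. Endpoint
ROIs for connectivity scoring are spheres of the bundle radius plus a
1.5-voxel margin: tracked fibers legitimately overrun the tube caps by a
couple of voxels before the FA stop fires, and terminal ROIs must absorb
that overrun for the endpoint rule to measure connectivity rather than
stopping accuracy. The generic `simulate_signal` contract keeps tight
radius-sized ROIs.

What these phantoms do **not** emulate: EPI distortion, eddy currents,
partial-volume T2 effects, restricted (non-Gaussian) diffusion, curved
crossing geometries at shallow angles, and anatomical variability. Tests
passing on them show the algorithms behave as designed under the stated
signal model — not that tracking on clinical data is accurate.

## Tensor model

Weighted log-linear least squares on `log(S/S0)` with weights S² (the
first-order variance correction for log-transformed data), solved per
voxel in batch. Non-positive signals are clipped to `1e-6·S0` before the
logarithm; voxels with more than 25% clipped measurements, or with
`S0 ≤ 0`, are flagged invalid and their FA is NaN — never silently zeroed.
A nonlinear fit was not used: at b ≤ 1500 with noiseless or high-SNR data
the log-linear estimator is exact or near-exact, and it is deterministic.
Principal directions carry a deterministic axial sign convention
(nonnegative dot with (1,1,1)/√3, ties broken on the first nonzero
component); eigenvalue gaps below 10⁻¹² mm²/s are flagged
planar-degenerate.

## dODF reconstruction

The dODF is the radial projection of the displacement PDF, itself the
discrete Fourier transform of the q-space signal magnitude. Two routes
share this definition:

**Explicit grid route** (`grid_qspace` → `compute_pdf` → `compute_dodf`):
each measured q-vector (direction scaled by √(b/b_max) to the shell
radius) is scattered to its nearest cell of an odd N³ lattice (default
N = 9, shell radius 4), mirrored antipodally, Hanning-tapered versus |q|,
FFT'd, and projected radially with trilinear interpolation at 25 uniform
radii over [0, 5] lattice units. This route is transparent and matches
the textbook construction, but on a coarse lattice the cubic anisotropy
of the scatter grid produces angular ripple comparable to the true lobes
— it is retained for inspection and for small problems, not for tracking.

**Shell-harmonic operator route** (`reconstruct_odf_field`, the default
for tracking): the single-shell signal is interpolated in angle by a
regularized even-order real spherical-harmonic fit (order 8 for ≥ 45
directions, 6 for ≥ 28, else 4; ridge 10⁻³), laid onto a finer lattice
(N = 21, shell radius 7, Gaussian radial profile σ = 1 cell, cosine taper
to 1.3× the shell radius), and the Fourier transform is evaluated
*exactly* at the off-lattice radial sample points ρ_j·v (25 radii over
[0, 0.9·(N//2)]). Every step is linear in the signal, so they compose
into one (vertices × gradients) matrix per gradient table; a whole-volume
reconstruction is a single matrix product. Band-limited angular
interpolation eliminates both scatter ripple and lattice anisotropy. The
grid parameters were chosen by a design study on randomly oriented
single-fiber and 90°-crossing voxels (the same checks now live in the
test suite): at 64 directions the operator recovers a single axis within
one mesh edge and exactly two crossing axes within 10° across random
orientations. At 25 directions crossings are resolved less reliably —
consistent with the physics of a single low-b shell — and the order-4 fit
is the practical limit.

The sphere mesh is a 3×-subdivided icosahedron (642 vertices, ~7–8°
spacing), kept as a full sphere with exact antipode pairing. A vertex is
a maximum iff it strictly exceeds its 1-ring and clears
`min(w) + 0.3·(max(w) − min(w))`; antipodal duplicates collapse to one
axis. The 0.3 relative threshold suppresses ripple maxima on a flat dODF
while keeping genuine secondary lobes; it is exposed in the API. A
constant amplitude field yields an empty maxima set (no direction
information).

## Spline tracking

State is four sliding control points p0..p3 in world-scaled voxel
coordinates (voxel index × voxel size, so step lengths and angles are
metric even with anisotropic voxels). One iteration samples the uniform
cubic B-spline segment

    s(u) = 1/6 · [u³ u² u 1] · B · [p0 p1 p2 p3]ᵀ,  u ∈ {0, ν, …, 1}

(B the standard uniform cubic basis with rows {−1,3,−3,1; 3,−6,3,0;
−3,0,3,0; 1,4,1,0}), appends the samples, then slides: p0 ← p1, p1 ← the
segment end point, p2 ← p1 + h·Q̂₁, p3 ← p2 + h·Q̂₂, where Q̂ is the dODF
axial maximum with the largest |dot| against the incoming chord
direction, sign-resolved to point forward. Defaults follow the intended
operating point: h = 1 mm (1.5 mm on 3 mm phantom grids), ν = 0.01,
θ_max = 60°, FA threshold 0.15, final-smoothing stride 20, safety cap
2000 iterations, minimum fiber length 10 mm.

Termination: FA ≤ threshold at the nearest voxel of the current end
point; turning angle between consecutive iteration chords ≥ θ_max
(computed from the p1→p2 chords, exactly as the stop criterion defines
it); leaving the volume; an empty maxima set; or the iteration cap. An
exactly perpendicular best axis is resolved to its + orientation and then
caught by the angle rule — so a 90° corner reports "angle", and
"no_direction" is reserved for genuinely missing orientation information.
dODF and FA lookups are nearest-voxel by design (half-integer ties round
toward +∞ for reproducibility); only the spline geometry is continuous.

Tracking is bidirectional from each seed (along the seed's
largest-amplitude maximum and its negation) and deterministic — there is
no randomness anywhere in the tracking path. Because consecutive segments
are not continuous, a finished trajectory is re-smoothed: every 20th
point (first and last always kept) becomes a control point, end points
are duplicated as phantom controls, and consecutive 4-point windows are
re-evaluated as B-spline segments. Duplicated-end smoothing pulls the
final point slightly toward the curve interior (by construction
`s(0) = (5c₀+c₁)/6`); with stride-20 control spacing on densely sampled
fibers the retraction is a small fraction of a voxel.

## Reference streamline trackers

Fixed-step Euler integration `r ← r + h·t(r)` with the tangent from the
tensor principal eigenvector or the best-aligned dODF maximum, bidirectional,
with the same termination rules and seed-direction convention as the spline
tracker so that comparisons isolate the propagation scheme. Voxel-boundary
(FACT-style) stepping is deliberately not emulated; this is a documented
difference from tensor-line implementations that step face to face.

## Tract analysis conventions

- Tract-mean FA pools all fiber points (point-weighted); per-fiber means
  are also returned. Voxel-mean FA counts each visited voxel once.
- Along-tract profiles orient every fiber to a common start — nearest
  endpoint to a user anchor, else a PCA rule on the endpoint cloud — then
  resample each fiber to n equal arc-length fractions (linear
  interpolation) and average **fiber-equally** per position, so long
  fibers do not dominate. With equal resampled counts per fiber this
  collapses to point pooling, which the tests exploit as an identity.
- ROI selection keeps fibers whose nearest-voxel trace intersects every
  ROI (AND) or any ROI (OR); truncation cuts at the first point inside
  the ROI scanning from the designated end, keeping the cut point.

## Evaluation

The spatial metric resamples both fibers to s = 1000 points with a
natural cubic interpolating spline parameterized by cumulative chord
length (two-point fibers fall back to exact linear interpolation), then
takes the mean pointwise Euclidean distance minimized over the two
traversal orders. It is symmetric, orientation-invariant, and a
pseudo-metric (zero self-distance, triangle inequality — property-tested
on random triples). Distances are reported in millimetres.

Connectivity uses the terminal rule — one fiber endpoint in each ROI of
the pair — with a pass-through mode behind a flag; when several
candidates match one truth fiber both the mean and the min distance are
reported, and non-connected bundles are excluded from the grand mean but
counted separately.

## Longitudinal model

`fit_lme` estimates `FA_ij = β0 + β1·Age_ij + b0_i + b1_i·Age_ij + ε_ij`
by REML via statsmodels MixedLM with an unstructured 2×2 random-effect
covariance (a diagonal option exists). Age is centered internally for
conditioning; fixed effects, their standard errors, the random-effect
covariance and the BLUPs are transformed back to the raw-age scale. The
REML criterion is invariant under this reparameterization. AIC/BIC use
parameter count 2 (fixed) + 3 (covariance) + 1 (residual), matching
lmer-style summaries; they are REML-based and not comparable across
fixed-effect structures. Boundary (near-singular) variance estimates and
non-convergence are surfaced as flags, never hidden. Note that the
intercept-related quantities (β0, Var(b0)) refer to age 0 and are
strongly anti-correlated with the slope terms; the estimable
between-subject variance is the one evaluated at the mean age, and the
tests check it there.

The longitudinal generator's defaults emulate an aging forceps-minor
trajectory: β0 = 0.713, β1 = −0.00474 FA/year, residual variance
1.43×10⁻⁴, eight subjects with three waves spaced 3 years and baseline
ages uniform on 52–66 years. Published variance components for such fits
are reported at age 0 with an unstated, near-degenerate intercept–slope
covariance; reused verbatim with independent draws they would imply
between-subject FA spreads far outside [0, 1]. The defaults therefore
use independence-coherent dispersions (Var(b0) = 10⁻⁴,
Var(b1) = 2.5×10⁻⁷) that reproduce a realistic ±0.03 between-subject
spread at the cohort ages; the covariance remains an explicit parameter.

## Problem sizes and determinism

The shipped phantoms are sized for a laptop-class single CPU: the
seven-bundle slab reconstructs and tracks all three methods from ~1500
ROI seeds in well under a minute, and the acceptance script's 500-cohort
coverage simulation completes in about one minute. Noiseless phantoms
make every tracking result bit-reproducible; all stochastic generators
take explicit seeds.

## Known limitations

- Single-shell acquisitions are the supported regime; multi-shell tables
  are gridded shell by shell but have not been a design target.
- The dODF operator assumes gradient directions expressed in the voxel
  axes (axis-aligned acquisitions); oblique affines are honored for
  geometry and I/O but not for rotating the gradient frame.
- At 25 directions the dODF resolves 90° crossings only marginally;
  secondary maxima below 30% of the dODF range are discarded by design.
- The endpoint connectivity rule is sensitive to where the FA stop fires;
  generous terminal ROIs (as used in the bundled phantom) are part of the
  measurement design.
- Euler trackers use fixed-step integration, not voxel-face stepping, so
  numeric parity with specific tensor-line software is not expected.
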