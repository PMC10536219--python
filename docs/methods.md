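# Methods

This note documents the models, conventions, and numerical choices behind
`croplab`, and what the synthetic experiments do and do not demonstrate.

## Polarimetric model

The dual-pol scattering vector k = (S_VV, S_VH)ᵀ is treated as zero-mean
circular complex Gaussian (fully developed speckle). Its 2×2 Hermitian
covariance C2 is estimated by spatial averaging of the outer products over
a moving window (default 5×5; edge pixels use the valid intersection with
the grid). `window=1` returns the rank-1 single-look covariances.

From the eigenvalues λ₁ ≥ λ₂ ≥ 0 of C2:

* **Degree of polarization** — the Barakat form
  `m = sqrt(1 − 4 det(C2) / Tr(C2)²) = (λ₁ − λ₂)/(λ₁ + λ₂)`, the ratio of
  polarized to total intensity, in [0, 1].
* **Dominant-scattering measure** — `β = λ₁/(λ₁ + λ₂)` ∈ [0.5, 1].
* **DpRVI** `= 1 − m·β` ∈ [0, 1].

Closed forms are used throughout (`λ₁,₂ = (Tr ± sqrt(Tr² − 4 det))/2`; the
discriminant equals `(c11 − c22)² + 4|c12|²` and is never negative), and
they are tested against a general Hermitian eigensolver.

Degenerate input conventions:

* zero (or subnormal-underflowing) trace — no signal in either channel —
  returns m = 0, β = 0.5 and DpRVI = NaN (nodata): an empty measurement
  carries no vegetation information;
* eigenvalues in (−10⁻⁹·Tr, 0) are clipped to zero (round-off guard);
  larger PSD violations raise `DegenerateCovarianceError`.

The intensity indices use linear power units: `RVI = 4σ_VH/(σ_VV + σ_VH)`
(the standard dual-pol form) and the ratio `σ_VV/σ_VH`.

## Refined Lee speckle filter

The filter estimates the local edge orientation from a 3×3 grid of
sub-window means of the total span (c11 + c22), picks one of 8 edge-aligned
half-windows (the side whose sub-mean is closer to the center's), and
applies the minimum-mean-square-error weight

    b = max(0, (var_y − σ_v²·mean_y²) / ((1 + σ_v²)·var_y)),   σ_v² = 1/L

computed on the span, identically to c11, c22, Re(c12), Im(c12). Defaults:
7×7 window, L = 4.4 equivalent looks (a typical effective-looks value for a
multi-looked C-band product); both configurable. Because one convex weight
multiplies all elements, the output at each pixel is a convex combination
of Hermitian PSD matrices and is therefore exactly Hermitian PSD: the
filter can never create negative powers or super-unity coherences.

## Seasonal time series

The acquisition plan is a strictly increasing day-of-year (DOY) grid,
nominally 16 dates at a 12-day cadence (DOY 121–301 by default; grids
starting DOY 122 or 124 reproduce the two other orbital-track plans).

* **Gap restoration.** One least-squares cubic in DOY is fitted per pixel
  to all observed dates of the season (≥ 5 required) and evaluated at the
  missing dates; targets outside the observed span are refused
  (interpolation only), and observed values are never altered. Restoration
  error on noiseless class trajectories is ≈ 0.001–0.05 at mid-season
  single-date gaps; for the most sharply peaked class (oat) the error can
  reach 0.08 at unfavorable gap positions near its rise — a known limit of
  a single global cubic, accepted for its robustness and closed form. The
  per-date mean/σ statistics of the anomaly screen are computed after
  restoration.
* **2σ anomaly screen.** Per field and date, the mean μ_d and standard
  deviation σ_d over the field's pixels define the 2σ interval; a pixel is
  discarded iff strictly more than half of its dates fall outside. Applied
  to training partitions only — held-out and regional test sets are never
  screened. Single-pixel fields are kept with a warning.
* **Seasonal maximum.** The maximum value and its DOY, earliest DOY on
  ties (deterministic and phenologically conservative); field-level
  summaries aggregate per-field maxima as mean ± standard deviation.
* **Dataset assembly.** Pixel membership in a field is
  center-in-polygon (the common zonal-statistics convention); pixels with
  any nodata date are dropped; extraction is deterministic.

## Classification

The 16-value series is the feature vector; no derived features. The three
classifiers are scikit-learn estimators with fixed settings:

* random forest — Gini impurity, `min_samples_split=2`, 120 trees, fixed
  `random_state` (bit-identical reruns);
* linear SVM — L2 penalty, squared-hinge loss, C = 1, balanced class
  weights, up to 10,000 iterations;
* QDA — Gaussian class-conditional model; a small ridge
  (`reg_param = 1e-4`) keeps class covariances invertible on small
  synthetic runs while leaving well-sampled fits essentially untouched.

Grid search uses stratified k-fold cross-validation (default k = 5,
seeded, shuffled); ties resolve to the first grid point. Train/test splits
are field-disjoint by construction: partitions are assigned to whole
fields, never to pixels, so spatially correlated pixels of one field can
not leak across the split.

Metrics are computed from the confusion matrix (rows actual, columns
predicted, class order fixed as fallow/soybean/oat): overall accuracy
`OA = 100·ΣX_ii/N` and per-class `F1 = 2TP/(2TP + FN + FP)`, with F1 = 0
(and a warning) for a class absent from both truth and predictions. Both
are authored here and cross-checked against brute-force recomputation and
`sklearn.metrics` in the tests.

Field-level identification assigns each field the class with the most
predicted pixels; exact ties (never observed at realistic field sizes)
break by the fixed class order with a warning. Percentages are rounded to
integers in tabular output; full precision is kept in JSON.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes; it
is the package's test bed and its default parameters are part of the study
conditions.

* **Trajectories.** Crops follow a double-logistic hump over a linear
  baseline ramp anchored to the DOY 120–305 season window; the composite
  maximum is placed exactly at the configured peak (soybean 0.59 at DOY
  258.9, rising from a ~0.30 early-season grass baseline and declining
  rapidly after the peak; oat 0.66 at DOY 212.5 with a broader hump).
  Fallow is a shallow sinusoid (amplitude 0.04, period 160 d, random phase
  per field) below its 0.65 maximum, so its max-min spread stays < 0.15
  and its peak date is arbitrary. Field-to-field jitter: σ ≈ 0.01 on the
  maximum, ~4 days on its timing. Each pixel adds a smooth (constant in
  time) offset with σ = 0.03. An optional second peak models oat
  over-seeded with perennial grass regrowing after harvest.
* **Speckle.** A target DpRVI d maps to the diagonal unit-trace covariance
  `diag((1+m)/2, (1−m)/2)` with `m = (−1 + sqrt(9 − 8d))/2` — the simplest
  family realizing any d in (0, 1]; an optional VV–VH correlation
  parameter makes harder (off-diagonal) scenes. Looks are drawn as
  independent circular complex Gaussian vectors; `output="slc"` stores one
  complex draw per pixel (looks then come from the spatial window:
  window w ⇒ w² looks), `output="c2"` stores the per-pixel average of
  `n_looks` outer products directly.
* **Default look count.** `n_looks = 150` emulates an analysis-ready
  covariance product: 3-look pixels averaged over a 5×5 window (75
  equivalent looks) with an adaptive filter roughly doubling the
  equivalent-look count in homogeneous areas. Controlled experiments pass
  other values explicitly (225 for round-trip fidelity; 25/9/4 for the
  noise-degradation study).
* **Geometry.** Axis-aligned rectangular fields (default 20×20 px ≈ 4 ha
  at 10 m) on a gapped grid; background pixels carry zero power and are
  masked downstream. Field geometry does not enter any tested computation.
* **Anomalies and gaps.** A configured fraction of each field's pixels
  follows another class's trajectory (cycling over the other classes);
  configured missing dates are omitted from the output and listed as
  restoration targets. The whole scene is a deterministic function of
  (config, profiles, seed).

### What the synthetic experiments show — and do not

Passing the synthetic suite shows the pipeline is self-consistent: the
estimator chain recovers the trajectories it was fed (to ±0.01 at 225
looks), the classifiers separate classes whose seasonal curves differ on
the scale the trajectory presets encode, and every stage is deterministic
under a seed. It does not demonstrate real-sensor performance: the
simulator has no radiometric trends (incidence angle, topography), no
temporal speckle correlation, no within-field agronomic gradients, and its
class trajectories are idealized single-family curves. Accuracies on
synthetic scenes (≈99% at 25 looks) are therefore upper bounds, not
forecasts, for real campaigns.

Two quantitative limits of the method itself, measured here:

* the multi-look DpRVI estimator is biased low at small look counts
  (eigenvalue repulsion inflates m̂): ≈ −0.026 at DpRVI 0.6 with 25 looks,
  vanishing by 225 looks;
* the 2σ anomaly screen saturates: the contamination itself inflates the
  per-date σ, so only dates where class trajectories separate by ≳ 0.1
  can flag a pixel, and with curves that genuinely coincide for half the
  season the strict more-than-half rule removes only ~55–75% of planted
  class-swap anomalies at realistic noise (while losing < 0.1% of clean
  pixels). The screen is a conservative outlier guard, not a reliable
  anomaly detector.

## Numerical conventions

* Rasters are row-major, pixel-center registered, 0-based; the affine
  transform is (x0, dx, y0, dy) with centers at x0 + (col + 0.5)·dx.
* In-memory nodata is NaN; on disk −9999 (float32 TIFF).
* PSD tolerance: determinants down to −10⁻⁹·max(Tr, 1)² pass validation.
* All simulator randomness flows through one `numpy` Generator seeded at
  scene level; classifier seeds are explicit arguments.
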