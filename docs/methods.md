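# Methods

This note documents the models, parameter choices, and numerical decisions
behind `fibrotex`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Imaging model and standardization

A CCE liver image is treated as a 2-D grayscale field in which fibrosis
appears as bright septa (width ~0.5–1 mm) around dark nodules (~2–5 mm).
ROIs carry physical pixel spacing and a tilt angle; the standardization
chain is fixed as **rotate → resample → detrend → rescale**:

* **Rotation** to zero tilt uses bilinear interpolation; the output is
  cropped to the largest axis-aligned rectangle provably free of fill
  (closed-form inscribed-rectangle formula, minus a one-pixel guard band).
  Tilts above 45° are rejected, and a crop below the 100 mm² minimum ROI
  area is an error rather than a silent degradation.
* **Resampling** is bilinear onto an isotropic 0.5 mm grid
  (`scipy.ndimage.zoom`, grid mode), preserving physical extent to within
  one pixel.
* **Detrending** subtracts the least-squares fit of `a + bx + cy + dxy`;
  the rank-revealing solve handles degenerate geometries. The residual is
  orthogonal to span{1, x, y, xy} by construction.
* **Rescaling** maps min→0, max→1; a constant image maps to 0.5 everywhere
  (any constant is texture-free; 0.5 avoids a divide-by-zero without
  privileging either end of the scale).

Derivatives use central differences with edge replication: gradient
magnitude is the Euclidean norm of the two components; the Laplacian is the
5-point stencil. Derivative images are **not** rescaled — they are honest
derivative fields — and feature classes that assume a bounded range
(histogram, Gaussian mixture, co-occurrence) shift-normalize them
internally. Coordinates are row-major, 0-based, pixel centers; positive
tilt is counterclockwise.

## The 55-feature catalog

The per-image catalog commits to a concrete 14 + 8 + 8 + 16 + 9 = 55
allocation over the five classes. Exact bin counts, lags and moment
normalizations are this package's own documented choices; the class
structure and the named predictors (histogram mean, mode/IQR, GMM sd of the
low component, AIC ratio, Voronoi inertial moments) are fixed.

* **Histogram (14)** — mean, SD, skewness, excess kurtosis, median, mode of
  a 64-bin histogram, IQR, mode/IQR, entropy (natural log), energy
  (sum of squared bin probabilities), p10, p90, p90−p10, coefficient of
  variation. Zero IQR imputes mode/IQR as mode/1e-6 (logged); moments of a
  constant image are 0 by convention.
* **Gaussian mixture (8)** — one- and two-component fits to the intensity
  sample. The one-component MLE is closed-form; the two-component fit is a
  restart-vectorized 1-D EM (k-means++-style init, 10 restarts, tol 1e-6 on
  the mean log-likelihood, ≤500 iterations, variance floor 1e-9),
  cross-checked against scikit-learn's EM in the tests. Features: means,
  SDs and low-component weight (components ordered by mean), standardized
  separation (Δmean over the weight-pooled SD), AIC₂/AIC₁ with
  AIC = 2k − 2 lnL (k = 2 and 5), and the log-likelihood gain. Samples
  above 1024 pixels are deterministically subsampled for the EM fit — at
  that size the mixture parameters of ROI-scale intensity samples are
  already stable, and the fit cost stays linear in the subsample.
  Note that on unit-interval data the log-likelihood is typically positive,
  so both AICs are negative and "two components not favored" corresponds to
  a ratio ≤ 1, equivalently a log-likelihood gain ≤ 3.
* **Autocorrelation (8)** — axis-wise normalized ACF over all non-circular
  pixel pairs; values at lags 1, 2, 4, 8 averaged over the axes;
  per-axis correlation lengths (linearly interpolated 1/e crossing, capped
  at lag 8); anisotropy (column/row length); sum of the axis-averaged ACF
  over lags 1–8. Zero-variance images yield zeros and unit anisotropy.
* **Co-occurrence (16)** — symmetric normalized GLCMs at distance 1 and
  0°/45°/90°/135° on a 16-level equal-width quantization; contrast,
  correlation, energy (angular second moment) and homogeneity per angle.
  Constant image: contrast 0, energy 1, homogeneity 1, correlation 0 by
  convention.
* **Voronoi polygons (9)** — seeds are regional minima of the σ = 1 px
  Gaussian-smoothed image with minima closer than 3 px suppressed (deeper
  one kept); pixels are assigned to their nearest seed; border-touching
  cells are discarded as clipping artifacts. Per retained polygon the n-th
  inertial moment is the mean |r − centroid|ⁿ in pixels; features are mean
  and SD of moments 1–3 and of polygon area, plus polygon density per cm².
  Fewer than 4 seeds (e.g. a constant image) is an error at decomposition
  level; inside full-stack extraction a Voronoi failure imputes that
  class's 9 entries as 0 with a logged warning, so the 55/165 cardinality
  contract is unconditional and vectors never contain NaN.

## Sparse fibrosis models

Both prediction models regress a histology reference on the 165 per-subject
features (ROI-averaged). Features are z-scored internally; the intercept is
never penalized; reported coefficients are back-transformed. The lasso path
runs over 100 log-spaced penalties from λ_max (the smallest penalty giving
the all-zero model) to 10⁻³ λ_max, solved by coordinate descent (tol 1e-8)
and verified against an independent solver in the tests.

Model size is chosen by a Gaussian AIC with the dispersion **fixed at the
null-model variance** of the response:

    AIC(λ) = RSS(λ) / Var(y) + 2 (df + 1),   df = active-set size.

The profile alternative n·ln(RSS/n) + 2(df+1), which treats the variance as
jointly estimated, degenerates whenever the path can interpolate: with
p = 165 features and n ≈ 46 subjects, RSS → 0 at the dense end of the path
and the criterion runs to −∞, always selecting a saturated model. Fixing
the dispersion at the only variance estimable without selection bias in the
p ≫ n regime keeps the criterion scale-invariant and selects the small
(≈2–7 feature) models this kind of analysis reports; the profile form
remains available via `dispersion="profile"`. AIC ties resolve to the
larger penalty (the sparser model). No cap is placed on model size; a
`max_predictors` option exists for fixed-size comparison tables.

Predictions are affine and unclipped — the texture score is continuous and
classification cutoffs live on its scale, so a "predicted Metavir" outside
[0, 4] is meaningful. There is no held-out validation, matching the
proof-of-concept design: in-sample correlations are optimistic and the
permutation-null test quantifies how much.

## Evaluation statistics

* **Correlation** — Pearson or Spearman with two-sided p-values; zero
  variance is an error, except inside the pipeline where an empty
  (intercept-only) model yields NaN with a logged warning.
* **ICC** — two-way random-effects, absolute-agreement, single-rater
  ICC(2,1) from the ANOVA mean squares, with the F-distribution /
  Satterthwaite confidence interval; pairwise reader ICCs are available.
  The implementation is validated against pingouin to its printed
  precision.
* **ROC** — AUC is the Mann–Whitney rank statistic (equals the trapezoidal
  area over all distinct cutoffs, tie-aware). The primary operating cutoff
  maximizes sensitivity + specificity, ties resolving to the lower cutoff;
  the point closest to (0, 1) is also stored, since both rules are current
  in this literature and they can disagree. 95% CIs for AUC, sensitivity,
  specificity and accuracy come from a class-stratified percentile
  bootstrap (default 2000 resamples, seeded); sensitivity/specificity/
  accuracy are evaluated at the full-sample cutoff within each resample. A
  threshold leaving one class empty flags that row and the remaining
  thresholds are still computed.
* **%-collagen segmentation** — RGB saturation is scaled by the
  stain-variability correction factor, a pixel's blue dominance is
  B − max(R, G), and %-collagen is the fraction of tissue-mask pixels above
  the intensity threshold (default 0.2 on the unit scale; monotone in
  blueness and exposed in the configuration).

## Synthetic cohort: what it emulates, and what it does not

The generator renders the reticular CCE texture as a Poisson-seeded Voronoi
tessellation (one Lloyd relaxation step for lobular regularity): cell
interiors at intensity 0.3, boundaries within half a septum width
brightened by the septum contrast, plus a bilinear shading ramp, optional
lattice tilt, and Gaussian noise. Severity s ∈ [0, 4] (the Metavir axis)
scales septum width 0 → 1.0 mm and contrast 0 → 0.6 linearly, so s = 0 is
trend + noise only. Defaults: nodule density 0.06 /mm² (≈4 mm lobules),
noise SD 0.05, trend amplitude 0.1, 32 × 32 mm ROIs at 0.5 mm/pixel. The
severity→conspicuity mapping has no published functional form; linear
scaling is this package's modelling choice and is deliberately simple.

References: three readers score `round(clip(s + N(0, 0.6), 0, 4))` — the
0.6 SD puts the simulated three-reader ICC in the ≈0.75–0.85 band typical
of expert hepatopathologists; %-collagen is
`exp(ln 2 + 0.55 s + N(0, 0.35))` clipped to [0, 100], i.e. 2% at F0,
≈18% at F4, log-linear in severity with a log-scale correlation near 0.85.
Cohorts are block-stratified across the five stages with uniform
within-stage jitter, mirroring severity-stratified recruitment.

Known limitations, hence what passing tests do *not* show about real data:

* No MR physics: no partial-volume blur, motion, coil shading beyond the
  bilinear ramp, or contrast-kinetics variability, and no 3-D structure.
* Per-ROI min-max rescaling removes absolute brightness, so
  absolute-intensity features (e.g. the histogram mean) are uninformative
  on synthetic images even though on real CCE images they carry
  contrast-uptake signal; severity discrimination tests therefore rest on
  the distribution-shape, derivative and Voronoi features.
* Early fibrosis is *easier* here than in reality: septum conspicuity
  grows linearly from zero, with no detection floor, so mild-vs-none
  classification does not reproduce the difficulty ordering seen on real
  images (where detecting F ≥ 1 is the hardest split and cirrhosis the
  easiest).
* Severity-0 images are pure noise whose smoothed minima still tessellate
  into nodule-scale cells, so Voronoi geometry alone does not separate F0
  from mild fibrosis; the contrast-sensitive classes carry that burden.

## Problem sizes and determinism

The test suite and the acceptance script use the cohort geometry the design
calls for — 46 subjects × 5 ROIs of 64 × 64 px — with 10 independent
cohorts for the end-to-end recovery check, 20 permutations for the null,
and 50 seeds for bootstrap-coverage checks; these sizes give stable
pass/fail behavior for the asserted bounds. Every random draw descends
from an explicit seed (`numpy` `SeedSequence` spawning per subject), so
cohorts, fits and bootstrap CIs are bit-reproducible, and the pipeline
writes the seed and package version into its run log.
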