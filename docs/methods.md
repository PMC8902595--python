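# Methods

## Synthetic cohorts

The generator emulates the *outputs* of a VBM preprocessing chain —
modulated, spatially normalized, smoothed gray-matter probability maps
on one shared grid — not the chain itself. Each subject volume is

    template + site shift + covariate effects + smoothed noise,

with the ASD group's mean reduced inside designated atlas regions.

- **Template.** Smoothed white noise (SD 0.08) on a constant GM level
  of 0.55, restricted to an ellipsoidal brain envelope (semi-axes 45%
  of each grid dimension). This mimics the spatial autocorrelation of
  smoothed GM maps without real anatomy; it has no cortical geometry.
- **Noise.** Per subject, white noise smoothed at the design FWHM and
  renormalized so the pointwise SD equals `noise_sd` (default 0.04) —
  smoothing shrinks pointwise variance by the kernel's sum of squares,
  and dividing by that factor keeps effect sizes stated in noise-SD
  units exact in the grid interior.
- **Effect.** A mean shift of `effect_size_d × noise_sd` subtracted
  from ASD volumes inside the effect regions, so the generative
  per-voxel Cohen's d equals `effect_size_d`. Covariate and site
  variance slightly inflate the empirical pooled SD, which is why the
  recovery test allows d = 1.2 ± 0.2.
- **Covariates.** Age ~ U(7, 15) years, sex ~ Bernoulli(0.8) coded 0/1
  (ASD cohorts skew male), TIV ~ N(1.45×10⁶, 1.2×10⁵) mm³. They enter
  volumes linearly (defaults 0.002 per year, 10⁻⁸ per mm³) — small
  relative to noise, so they are nuisance structure for the GLM to
  remove, not the dominant signal.
- **Sites.** Default sizes mirror a multi-site pediatric ASD study:
  GU 55 TDC / 51 ASD, OHSU 56/37, UCLA 16/16. Each site gets a scalar
  intensity offset ~ N(0, `site_shift_sd`) over the envelope.
- **Severity scores.** For ASD subjects only: the standardized regional
  summed volume `z` plus Gaussian conditional noise,
  `score_z = r·z + √(1−r²)·ε`, mapped to a mean-10/SD-3 scale, so the
  population correlation with regional volume equals the target r.
  Scores are stored as floats; rounding to integer scales happens only
  on TSV output, and correlations always use the pre-rounding values.
- **Smoothing.** Separable Gaussian with σ = FWHM / (2√(2 ln 2)) per
  axis (FWHM in mm, converted to voxels; default 6 mm on a 2 mm grid).
  Boundary handling is mirrored reflection — a convention of this
  implementation, chosen so that kernel mass is conserved under the
  symmetric reflection.

**What passing tests on these cohorts do and do not show.** They show
the statistics and the machine-learning protocol are implemented
correctly: calibrated null behaviour, leak-free cross-validation, exact
cluster extraction, controllable effect recovery. They do not show
anything about real T1 images: the cohorts have no cortical geometry,
no segmentation or registration error, no white-matter channel, and
site effects are a scalar intensity shift rather than scanner-specific
contrast differences.

## Voxelwise GLM

Per voxel, OLS of `value ~ 1 + group + covariates` (group coded ASD=1);
t for the group contrast with df = n − p, two-sided p from the t
distribution. With no covariates this reduces algebraically to the
pooled-variance two-sample t (asserted to 1e−10 in tests). The default
reported direction is TDC > ASD (GM reduction in patients); both
directions are available. One- vs two-sided reporting is not prescribed
by the workflow; two-sided p with a direction tag is this package's
choice. The null-calibration test runs the generator with
`smoothing_fwhm = 0`: smoothing induces spatial correlation between
voxel tests, which would invalidate the binomial bound the test uses,
and the property under test is GLM calibration, not smoothing.

Masking: a voxel enters the analysis iff its value exceeds the absolute
threshold (default 0.1) in **every** subject — the SPM absolute-masking
convention; a cohort-mean rule is available (`rule="mean"`).

## Cluster extraction

Supra-threshold voxels are grouped by `scipy.ndimage.label` with a
6/18/26-connectivity structuring element (default 26, the common
neuroimaging convention; the workflow source is silent on this), then
filtered by the extent threshold (default 50 voxels) and sorted by size
descending (ties: lowest minimum linear index). The peak is the voxel
of maximum |statistic|, ties broken by lowest linear index. Tests
verify exact agreement with an independent BFS flood-fill oracle.

## Searchlight

- **Sphere.** All integer offsets with ‖δ‖ ≤ r, default radius 3
  voxels for production use (≈ 6 mm at 2 mm grid, matching the
  smoothing scale and common searchlight practice — the radius is not
  prescribed by the workflow and is a required-visible configuration
  value). The desk-scale analyses and tests here use radius 2 on the
  16³ grid so the sphere (33 voxels) stays small relative to the toy
  brain. Out-of-grid and out-of-mask voxels are clipped per center.
- **PCA.** Eigendecomposition of the training covariance via SVD of the
  train-mean-centered matrix. k is the *minimal* count with cumulative
  variance fraction ≥ the threshold (default 0.8), with 1e−9 absolute
  slack to absorb round-off on exact-tie spectra. The test set is
  centered with the training mean — never its own. A zero-variance
  training block degenerates to k = 1 with a warning flag. Implemented
  directly (rather than via `sklearn.decomposition.PCA`) because the
  minimal-k retention contract differs from sklearn's selection rule on
  tie cases; sklearn is the cross-check oracle in tests.
- **SVM.** L2-regularized squared hinge without intercept, solved by
  Newton iterations on the active set with backtracking (the objective
  is piecewise-quadratic and convex; convergence takes a handful of
  iterations at the k ≤ ~10 dimensions PCA leaves). Prediction is
  ASD (+1) iff `wᵀx > 0`; an exact tie goes to TDC (−1), matching the
  strict inequality of the decision rule. Cross-checked against
  liblinear (`LinearSVC`) to 1e−5 in tests; the bespoke solver is
  ~10–30× faster per tiny fit, which the per-voxel loop needs.
- **Cross-validation.** Stratified 5-fold, 5 repeats (the workflow says
  folds are drawn "randomly"; stratification is this package's choice
  because imbalanced sites risk single-class test folds). Fold
  assignments are drawn once per repeat and shared across voxels,
  making the map a paired comparison across space. The map value is the
  mean of the 25 per-fold accuracies; stored fold accuracies allow an
  exact independent recount.
- **Thresholding.** Accuracy ≥ 0.70 (non-strict — the threshold rule's
  strictness is unstated; ≥ is used and documented) with the 50-voxel
  extent, then atlas partitioning: per region the union of
  cluster ∩ region voxels, dropping regions under `min_overlap`.

## Region evaluation

- **Families.** PCA+Ridge (`sklearn.RidgeClassifier`, ±1 targets as a
  regression, with an unpenalized intercept — without one, centered
  data degenerate), PCA+SVM (the solver above), and Bagging
  (`sklearn.BaggingClassifier` over Gini decision trees; rows drawn
  with replacement, features without — the default convention of that
  implementation; both exposed as flags; score = mean estimator vote).
- **Search space.** PCA variance grid {0.6, 0.7, 0.8, 0.9, 0.99} (the
  stated 0.6-to-0.99-by-0.1 grid cannot reach its own endpoint, so the
  endpoint is included explicitly); C and α log-uniform on
  [1e−10, 1e10]; estimators 3–30; sampling fractions uniform [0.5, 1].
  Randomized search with a default budget of 30 draws per inner loop
  (trial counts are not prescribed; 30 covers the small grid and
  samples the continuous ranges adequately), scored by inner 5-fold CV
  accuracy, ties to the first draw.
- **Nested CV.** Stratified outer folds (default 5 × 10 repeats);
  tuning sees only the outer-training portion; predictions are pooled
  within a repeat and metrics averaged over repeats. ASD is the
  positive class for SEN/SPE throughout.
- **Multi-site.** Tune and fit on the training site, predict the pooled
  held-out sites once; per-site metrics are also recorded (pooling
  vs averaging is not prescribed; both are reported, pooled is the
  headline).
- **Permutation test.** Observed = stratified 5-fold CV accuracy with
  the tuned configuration; each of n_perm (default 5000; desk-scale
  runs use 200) permutations redraws labels and repeats the identical
  fold procedure. p is the exact exceedance fraction
  (#{null ≥ observed}/n_perm); p = 0 is therefore possible and is
  rendered as "< 1/n_perm" in human-readable output while the raw
  fraction is stored. The configuration is frozen from the real-label
  fit by default (re-tuning inside every permutation is configurable
  but off — the protocol source is silent, and freezing keeps
  desk-scale runtime feasible while remaining valid: the null
  permutations then test the *selected* model, a slightly conservative
  choice).
- **Selection.** A region is a biomarker iff, for its best family (by
  nested-CV accuracy), |SEN − SPE| ≤ 20 percentage points on every
  provided evaluation setting and permutation p < 0.05. The gap rule is
  non-strict at the boundary (≤ 20 passes); the significance rule is
  strict (p = 0.05 fails).

## Severity correlation

Regional volume = in-region intensity sum × voxel volume (modulated
maps integrate to tissue volume; a mean-intensity option exists).
Pearson r with two-sided p from the t transform on n − 2 df, computed
within the ASD group (severity instruments are administered to
patients), NaN scores dropped pairwise. Pearson rather than Spearman
matches the parametric-style r/p reporting the workflow mirrors; the
choice is this package's and is configurable only by computing on
ranks externally. No multiple-comparison correction is applied across
region × score pairs.

## Determinism

Every stochastic operation takes a seed; one global seed hash-derives
per-stage seeds (SHA-256 of stage label + seed, reduced below 2³¹), so
stages can be rerun in isolation and reproduce their artifacts exactly.
Documented tie-breaks: cluster ordering and peaks (lowest linear
index), hyperparameter ties (first draw), SVM decision ties (negative
class), argmin ties in atlas region growing (lowest label).

## Problem sizes

The bundled analyses and tests run on 16³ grids (≈ 1,600 in-mask
voxels), 60–90 subjects, 5 × 5-fold searchlight CV, 10-draw search
budgets, and 200-permutation tests. These sizes make every stage of the
protocol measurable on a single CPU while keeping the statistical
checks (binomial null bounds, Fisher-z coverage, Dice recovery) well
powered; production use on real cohorts scales the same code to full
resolution by configuration.

## Known limitations

- The toy atlas is a Voronoi partition of an ellipsoid — contiguous
  regions, but no anatomical shapes or names.
- Site effects are scalar intensity shifts; no scanner contrast or
  resolution differences, no site-by-effect interaction.
- The searchlight smears signal up to one sphere radius beyond a true
  region's boundary; neighbouring regions can enter the candidate set
  (and are then filtered at the feature level, as the worked example
  shows).
- `RidgeClassifier` at extreme α (≥ ~1e12) can emit all-one-class
  predictions on small samples, which is handled as chance-level
  performance, not an error.
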