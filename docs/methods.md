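# Methods

`esotox` re-implements, as a tested library, a multi-omics pipeline for
predicting symptomatic (grade ≥ 2) acute radiation esophagitis (ARE) in lung
cancer patients treated with IMRT, from three per-patient inputs: the
planning CT, the 3D dose distribution, and the contoured esophagus.  Because
no patient data ship with the package, a synthetic phantom cohort generator
is a first-class module: it reproduces the statistical structure the
analysis assumes, so every downstream stage is testable end to end.

## Phantom cohorts

Each synthetic patient is a cylindrical esophagus of radius 11.5 mm and
length 90 mm on an isotropic 1 mm grid (48 × 48 × 96 voxels), giving a mask
of ≈ 37 cc.  Defaults are the study conditions: 161 patients per cohort and
a target event prevalence of 31.7%.

* **CT texture.** Inside a bounding box around the mask, HU values are a
  correlated Gaussian field: white noise smoothed with a Gaussian kernel
  whose width is the texture correlation length, re-normalised to unit
  variance, scaled to SD 30 HU around a mean of 40 HU and clipped to
  [−100, 175] HU.  A fraction (default 5%) of mask voxels is replaced by
  −400 HU "cavity" voxels, which the HU-window refinement later removes.
  The per-patient correlation length is log-normal around 3 mm (log-SD
  0.35); it is the latent that makes GLCM texture vary between patients —
  fixed-bin-count discretisation over each patient's own min–max makes
  texture features invariant to the texture *amplitude*, so roughness, not
  amplitude, carries signal.
* **Dose.** A prescription-scaled field with a lateral Gaussian falloff
  around an axis offset 10 mm from the tube axis, a longitudinal gradient of
  2 Gy/cm, and additive voxel noise (SD 1 Gy), clipped at 0.  The
  per-patient lateral falloff is log-normal around 12 mm (log-SD 0.30) and
  is the latent behind the dose-moment signal.  The prescription comes from
  the patient's clinical covariates (45–70 Gy, median 60 Gy).
* **Clinical covariates** are drawn with the marginal frequencies of the
  modelled cohort (88.2% male, 54.0% concurrent chemoradiotherapy, etc.).
  They carry no planted effect by default, mirroring the finding that
  clinical factors alone predict poorly.
* **Outcome model.** Labels are Bernoulli draws from a logistic model on
  *planted features*: named features actually measured on each generated
  case (default: `original_glcm_Contrast_bin20` and `dose_moment_eta_200`,
  both with log-odds coefficient 1.8 per SD — chosen as a "strong" effect,
  latent AUC ≈ 0.9).  Feature standardisation uses a Monte-Carlo calibration
  sample (default 2000 cases), and the intercept is root-found (Brent) so
  the calibration-sample prevalence matches the target.  With no planted
  effects the intercept is the closed form `logit(target)`.
* **Determinism.** One master seed; per-case seeds derive from
  `SeedSequence([master, case_index])`, so extending a cohort never
  reshuffles earlier patients.  Label draws use a dedicated per-case
  substream.  The label path computes planted features on the mask bounding
  box only and is bit-identical to full-volume generation.

What the phantom does **not** emulate: anatomy (no curvature, no
neighbouring organs), CT reconstruction physics, realistic treatment-plan
dose shapes, or correlations between clinical covariates and dose/texture
beyond the prescription.  Passing tests therefore demonstrate correctness
and recoverability of the pipeline under its own assumptions, not clinical
performance.

## Feature extraction

Volumes are resampled to 1 × 1 × 1 mm (linear for images, nearest for
masks; resampling an already-isotropic grid is the identity), the dose grid
is enforced onto the CT grid, and the esophagus mask is refined by the
closed HU window [−150, 180] to remove air cavities.  By default the
refined mask is used for both CT and dose features
(`hu_window_scope="both"`); `"ct_only"` is available.

* **Radiomics** — per image variant (original, the 8 single-level `coif1`
  wavelet band reconstructions, LoG at σ ∈ {1, 2, 3} mm): 12 first-order
  statistics, plus per bin count (defaults
  [20, 30, 40, 50, 80, 100, 150, 200, 250, 300]) discretised entropy and
  GLCM/GLRLM texture.  Discretisation uses fixed bin *count* with
  equal-width bins over the in-mask min–max.  GLCM accumulates the 13 unique
  3D offsets into one symmetric matrix (merged strategy); GLRLM computes
  per-direction run-length features and averages the 13 directions.
  Wavelet bands are reconstructed to full resolution so the mask applies
  unchanged; the LoG filter operates on the mean-free field to cancel the
  truncated kernel's DC bias.  The feature count follows the documented
  formula `variants × (12 + bins × (1 + 6·GLCM + 7·GLRLM))`; parity with
  any particular published feature count is not attempted, since full
  extraction configurations are rarely printed.
* **Dosiomics** — three blocks: (1) the 63 scale-invariant 3D dose moments
  η\_pqr = μ\_pqr / μ₀₀₀^(1+(p+q+r)/3), central moments of the dose field in
  physical mm about the dose-weighted centroid, volume-element weighted
  (orders 0–3 per axis; the all-zero index is identically 1 and excluded).
  Volume-element weighting is what makes η stable (< 2% drift) under grid
  resampling — the defining property; under dose rescaling D → kD the exact
  covariance is η → k^(−(p+q+r)/3)·η.  (2) DVH metrics: V at
  {0.99, 1, 5, …, 70} Gy (in % and cc; `V0.99` is configurable as an
  absolute 0.99 Gy threshold, the default, or as a fraction of the maximum
  dose) and D at {2, 5, 50, 95, 98}%, computed from the exact sorted dose
  sample with linear interpolation; "receiving" is strictly-greater-than.
  (3) original-image dose texture via the radiomics operators.  All names
  carry the `dose_` prefix.

## Feature selection (stability selection)

1. 100 iterations; each draws ⌊0.7 n⌋ patients without replacement,
   stratified by outcome so both classes are always present (stratification
   is a design choice; it guarantees valid F-tests).  A feature survives an
   iteration iff its subsample variance is positive and its one-way ANOVA
   F-test p-value against the label is ≤ 0.1.
2. The 10% most frequent survivors are kept (quota over features surviving
   at least once, configurable; floor of 10), ties broken deterministically
   by (frequency desc, median p asc, name).
3. Greedy correlation pruning in rank order removes any feature with
   |Pearson r| > 0.5 against an already-kept feature (the more stable member
   of a violating pair wins).
4. Nested prefixes of the pruned ranking are scored by mean validation AUC
   of a ridge classifier over 20 repetitions of stratified 5-fold CV;
   the smallest prefix within one standard error of the best mean is
   selected.  Exhaustive subset search is infeasible and published subset
   sizes are small, so nested prefixes are the search space.  The inner
   ridge uses the exact closed-form solve (algebraically identical to
   `sklearn`'s `RidgeClassifier`; the equivalence is unit-tested).  Note
   that CV fold estimates share patients, so on pure-noise tables the
   prefix means spread by far more than the nominal SE of the mean; the
   parsimony rule keeps subsets small but cannot guarantee size one.

## Modelling and evaluation

* **Easy-ensemble ridge.**  The ridge penalty is grid-searched (13
  log-spaced values 10⁻³…10³) by stratified tenfold CV on the training
  cohort (per-fold standardisation).  Ten bags are then drawn: each takes a
  stratified 2/3 subsample of the training patients and balances classes by
  keeping every minority-class patient plus an equal-count majority draw;
  each bag standardises on its own sample and fits a ridge classifier.  The
  ensemble score is the arithmetic mean of bag decision scores — an exact
  linear function of the features, whose pooled coefficients the results
  object exposes.  Ridge margins become probabilities by logistic (Platt)
  calibration on the training scores; the accuracy threshold is 0.5.
* **Repeated splits.**  30 independent stratified splits with test size
  ⌈n/3⌉ (161 → 107 train / 54 test); AUC (rank-based, ties ½) and ACC
  are recorded on both cohorts.  Summaries are mean ± sample SD with the
  95% CI `mean ± 1.96·SD/√30` (the normal approximation of the mean over
  the split series).  Model comparisons use a two-sided paired t-test across
  shared splits (a sign-flip permutation test is available); a constant
  zero difference yields p = 1 with a warning, a constant non-zero
  difference p = 0.
* **Selection placement.**  For evaluation, the selection procedure is
  re-run inside every training cohort, so test metrics never see features
  chosen on their own patients — on null cohorts a single cohort-level
  selection inflates mean test AUC to ≈ 0.69, whereas in-training selection
  is unbiased per split.  The cohort-level selection remains available (and
  is what the pipeline's `select` stage reports), because the combined
  model and nomogram need one shared feature list across the 30 split
  models.
* **Combined model and nomogram.**  The combined model averages the split
  models' scores.  The nomogram maps the RadScore (the pooled linear score;
  at the reference patient — every feature at its training mean — it equals
  the standardised intercept) affinely to a 0–100 total-points axis over
  the observed cohort range; per-feature points are each feature's share of
  the total score range; probability is the calibrated logistic of the
  RadScore and is strictly increasing in total points.  The nomogram is
  exported as a table plus probability function; no graphic is rendered.

## Problem sizes and numerical choices

Replication-scale runs (the acceptance script and the long acceptance test)
use the reduced extraction profile — original image only, bin counts
{20, 50}, GLCM texture, GLCM-only dose texture (≈ 154 features) — so that a
10-master-seed recovery sweep, a 30-split signal experiment and three
30-split null cohorts complete in minutes on one core; the full default
profile is exercised on small volumes in the unit tests.  Outcome
calibration uses 1000–2000 Monte-Carlo cases; the unit tests verify fresh
prevalence against bands derived from the binomial sampling error of the
scales used.  The null operating point is estimated over three null
cohorts because the 30-split mean is a per-cohort quantity with ≈ 0.05
across-cohort SD.

Degenerate inputs are defined, not patched over: constant regions give zero
variance/entropy/contrast and correlation 1; single-voxel masks refuse
texture; zero total dose refuses the moment centroid; an empty refined mask
is an error; one-class label vectors refuse AUC and model fits.

## Known limitations

* Phantom realism is deliberately minimal (see above); recovery results
  quantify pipeline behaviour, not clinical effect sizes.
* GLSZM/NGTDM texture families and shape features are not implemented.
* DICOM-RT parsing is out of scope; volumes are NRRD/NIfTI.
* The nomogram is tabular; no rendered figure.
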