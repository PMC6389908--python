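# Methods

## Model and procedure

The risk model is a two-step ("supervised PCA") linear classifier for
case/control status on normalized log2 miRNA expression.

**Screening.** Each miRNA is tested in its own logistic regression with
the clinical covariates sex (0/1), age (years) and APOE ε4 allele count
(0/1/2) plus an intercept; the Wald z = α̂₄/SE(α̂₄) of the miRNA term
summarizes its adjusted association. Selection keeps miRNAs with
|z| ≥ T. The absolute value is used because protective and
risk-increasing markers are equally informative; ties at |z| = T are
included so the grid endpoints behave deterministically. Fits that fail
(constant miRNA, perfect separation, singular information) are flagged
non-converged and excluded from selection rather than raising —
screening thousands of probes must tolerate individual degenerate
fits. No multiple-testing correction is applied: the z-values are used
only for ranked pre-selection, not inference.

**Projection and risk score.** PCA is fit on the selected submatrix
with per-feature centering and no variance scaling (all features share
the log2 expression scale; a scaling switch is not offered because it
would change the meaning of the loadings lⱼ). Components are capped at
min(n_features, n_samples − 1); each loading column is sign-fixed so
its largest-magnitude entry is positive, which makes serialized models
reproducible across linear-algebra backends. The PC-score logistic
model is fit **without an intercept**, matching the parameterization
under which published prognostic-index cutoffs (e.g. 0.281 for
AD-conversion) are defined; an `intercept=True` option exists for
sensitivity analyses. The prognostic index PI = Σ βᵢ·PCᵢ is therefore a
fixed linear functional of centered expression, and classification uses
the strict rule PI > cutoff.

**Cross-validated grid search.** T runs over 0.1–5.0 in steps of 0.1
and m over 1–10 by default (500 cells; both grids are configurable —
e.g. `m_grid=range(1, 51)` reproduces a wider search). Folds are
stratified by class: with case:control ratios of ~3.5:1, unstratified
folds can lose the minority class entirely. Per fold, z-values and the
selection are recomputed on the 9/10 training portion only — selection
lives inside the loop, never before it, so the held-out AUC is not
inflated by selection bias. A fold is valid for a cell only if ≥ 1
miRNA passes T and the PC fit converges; a cell's score averages its
valid folds (`n_valid_folds` is recorded; cells with none are carried
as missing rather than being scored 0.5, which would distort the
surface). The per-fold average is the default scoring; pooled
out-of-fold scoring is available as `scoring="pooled"`. The optimum is
the cell with maximal mean AUC, ties broken toward larger T (fewer
miRNAs, the more parsimonious model) and then smaller m. The final
model refits z-values, selection, PCA and betas on the complete
discovery cohort, with m capped at the available components.

**Evaluation.** AUC is the Mann–Whitney probability that a random case
outscores a random control (ties ½), computed from mid-ranks; the ROC
curve is enumerated at every distinct score with strict-`>`
classification, so its trapezoidal area equals the rank statistic
exactly. The PI cutoff maximizes the unweighted mean of sensitivity and
specificity on the **discovery** ROC curve (equivalent to the Youden
index argmax); ties prefer higher sensitivity, then the lower
threshold. Confusion-matrix ratios with zero denominators are reported
as missing, never as 0. Proportions are rounded only at the reporting
layer (4/22 = 0.1818… prints as 0.18).

## Normalization

Background statistics are computed per array from that array's
negative-control probes (standard 3D-Gene-style practice; a global
background would leak between arrays). Trimming removes
`ceil(0.05·k)` values from each tail, so 5 % of 20 removes exactly one
per tail; the retained values give a sample-SD (denominator k′−1)
threshold `mean + 2·SD`. The threshold is strict: a signal exactly at
it is floored. The floor, "minimum effective value − 0.1", is applied
per array on the log2 scale. Undetected entries are imputed with the
per-miRNA mean of normalized values (final-scale consistent), **then**
arrays are standardized by subtracting each array's internal-control
mean deviation from the across-array average — subtraction in log2
space being division in linear space. The order (impute, then
standardize) and the across-array-mean anchor are documented
conventions; the anchor choice only shifts all samples by a common
constant and cancels from every downstream contrast. A miRNA undetected
in every sample is an error (its mean is undefined), as is an array
with no effective signals (its floor is undefined).

## Synthetic cohorts

The generator produces expression directly on the normalized scale:
per-miRNA baselines μⱼ ~ N(8, 1.5) log2 units and SDs σⱼ ~ U(0.5, 1.2),
chosen to resemble serum-array log2 intensity ranges; consecutive
miRNAs form blocks of 20 sharing a latent factor with within-block
correlation 0.3 by default, emulating co-regulated miRNA families.
Planted miRNAs add `effect_size·σⱼ` to case means, so `effect_size` is
a standardized shift. Covariates are drawn per group from an elderly
AD-study-like model (cases: mean age 79.2 vs 71.7, fewer males, mean
APOE ε4 count 0.5 vs 0.2; SD of age 6 years, floored at 60); the
`covariate_effect` knob linearly interpolates the case parameters
toward the control ones, so 0 gives identically distributed groups —
the correctly specified null for the adjusted per-miRNA model — and 1
the full contrast. This group-conditional construction (rather than a
population draw with a logistic assignment) keeps the group sizes
exact, which the fixed-size discovery/validation design needs. The
split is a seeded stratified random half within each phenotype; exact
age-distribution matching between halves is not attempted.

Raw arrays are derived by inverting the normalization: negative
controls are drawn around a background level, and each signal is
`trimmed_mean + 2^(value + arrayshift)` with the per-array shifts
mean-centered in log2 space; three internal-control probes carry fixed
targets plus the same shift. Round-trip tests are therefore exact by
construction at zero measurement noise. The prospective generator
draws converters from the case distribution with effects scaled by
`separation` and non-converters halfway between case and control
(`separation/2`), so `separation=0` collapses the groups.

What the generator does **not** emulate: array spatial artifacts,
probe-sequence effects, batch structure beyond per-array shifts,
non-Gaussian intensity tails, or realistic linkage between covariates
and specific miRNAs. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under its own
assumptions, not performance on real serum arrays.

## Problem sizes used in tests and the acceptance script

The strong-signal end-to-end run uses 1022 cases + 288 controls (half
discovery), a 500-miRNA panel with 10 planted miRNAs at standardized
effect 1.5, and the complete default 50 × 10 grid. The
median-over-seeds agreement study uses ten runs of 500 cases + 150
controls on a 250-miRNA panel with a coarse T grid (0.5 steps, m ≤ 5);
the null-calibration run uses 150 + 150 samples, 200 miRNAs and a
small grid. These reduced panels preserve the dimensional regime
(features ≫ informative features, features comparable to samples)
while keeping a full run in tens of seconds; the pipeline itself has
no size-dependent switches, so results at the full 2562-probe panel
differ only in compute time.

## Numerical choices

* Logistic fits use Newton's method (statsmodels) with
  observed-information standard errors; the test suite cross-checks
  them against a hand-written IRLS implementation to 1e-6.
* PCA uses SVD of the centered matrix; input arrays are coerced to a
  canonical C-contiguous layout first so that means and decompositions
  are bit-reproducible regardless of how the caller's DataFrame is
  stored (serialized models from in-memory and TSV round-tripped data
  are byte-identical).
* Expression TSVs are written with `%.17g` and parsed with
  `float_precision="round_trip"`, making write → read lossless.
* Mutual Rank excludes self-correlations, starts ranks at 1 and gives
  tied correlations average ranks — the convention that keeps MR
  symmetric under ties. Edge filters (MR < 20, PCC > 0.4) are strict
  on both sides, and the hub rule (degree > 25) is strict.
* Seeds: every stochastic component takes an explicit seed;
  `numpy.random.default_rng` generators are never shared across
  stages.

## Known limitations

* Validation-cohort accuracy at the discovery-chosen PI cutoff is
  sensitive to prevalence differences between cohorts; no recalibration
  is offered.
* Non-convergence handling excludes miRNAs rather than falling back to
  penalized fits, so extremely separable markers can be dropped at the
  screening stage.
* The LASSO baseline uses the liblinear coordinate-descent solver with
  a 10-value penalty path; it is a comparison baseline, not a tuned
  competitor.
* Co-expression networks operate on whatever expression or correlation
  matrix they are given; curated external co-expression databases and
  miRNA-target annotation are out of scope.
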