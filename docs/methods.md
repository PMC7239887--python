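# Methods

## Model and objective

The core model is linear elastic-net regression of ICV-adjusted gray
matter volume (GMV, in % of intracranial volume) on p mixed-type
predictors. We minimize

    f(β₀, β) = (1/2n)‖y − β₀ − Xβ‖² + λ ( α‖β‖₁ + (1−α)/2 ‖β‖₂² )

with mixing weight α ∈ [0, 1] (α = 0 ridge, α = 1 lasso) and overall
penalty λ ≥ 0. This is the dominant convention for the elastic net; other
parameterizations rescale λ, so printed λ values are comparable only
within one convention. Columns are standardized to mean 0 and quadratic
mean 1 ((1/n)Σx² = 1); the intercept then decouples as β₀ = mean(y), and
coefficients are reported back on the original predictor scale.

The solver is cyclic coordinate descent on the Gram formulation
(G = XᵀX/n, c = Xᵀ(y−ȳ)/n): each update is

    β_j ← S(c_j − Σ_{k≠j} G_jk β_k, λα) / (G_jj + λ(1−α)),

with S the soft-thresholding operator. Gram updates cost O(p) per
coordinate instead of O(n), which is what makes the resampling loop cheap;
the inner kernels are numba-compiled. Convergence is declared when the
largest coefficient change in a sweep falls below `tol` (default 1e−7;
default `max_iter` 10 000 sweeps); non-convergence warns and returns the
fit flagged. Correctness is checked in the test suite against an
independent proximal-gradient (FISTA) solver, the closed-form ridge
solution, OLS at λ = 0, and the KKT conditions.

Numerical conventions worth knowing:

* λ grid: 100 log-spaced values from λ_max = max_j |c_j| / max(α, 0.001)
  down to 1e−4·λ_max. The α floor keeps λ_max finite for ridge.
* A variable counts as *selected* when its original-scale |β| > 1e−10
  (absorbs floating-point dust; the penalty itself produces exact zeros).
* Ties in the CV argmin break toward the larger (more parsimonious) λ.
* Columns that are constant within a training subset are dropped from that
  fit (coefficient pinned at 0) rather than crashing the split.

## Choice of λ: CV argmin vs the one-standard-error rule

λ is tuned per training set by internal 10-fold cross-validation over the
shared grid (folds from a seeded shuffle, re-centered per fold with
fold-training means). `CVResult` exposes both the curve argmin
(`lambda_min`) and the largest λ whose mean CV MSE is within one standard
error of the minimum (`lambda_1se`). The outer loop refits at the 1-SE λ
by default (`rule="1se"`). The reason is scientific rather than numeric:
the argmin systematically under-penalizes on data of this shape (a few
real effects among ~100 collinear candidates at n ≈ 300), yielding 20–40
nonzero coefficients per split so that dozens of null variables are
"selected" in nearly every split and selection frequency stops ranking
anything. The 1-SE rule — the standard parsimonious alternative in
penalized regression practice — restores sparse per-split models (~4–8
variables) and a graded frequency spectrum, which is the regime the
stability-selection design presupposes. `rule="min"` is available
throughout for sensitivity analyses.

## Stability selection and benchmarks

The outer loop draws S = 1000 independent train/test splits (90/10;
test size = floor(0.1·n), so n = 293 gives 264/29). Per split:
standardization statistics come from the training rows only (anything
else leaks test information), the inner CV picks λ, the model is refitted
on the full training set, and we record the selected set, original-scale
coefficients, held-out MSE, held-out adjusted R² (with p = number of
selected variables; undefined — recorded as NaN — when a split selects
more variables than the test set can support), and the Null Model MSE
(constant prediction at the training mean). Reported quantities are means
over splits; variable importance is the selection count, with ≥100 of
1000 splits as the default "most predictive" reporting threshold (scaled
proportionally when S differs). An α sweep (0 to 0.2 in steps of 0.01,
same split list reused so differences isolate α) reproduces the expected
endpoints: ridge keeps every variable in every split; stronger α prunes
null variables harder.

Shrunken coefficients are biased toward zero, so no p-values or
confidence intervals are attached to elastic-net estimates. Instead two
follow-ups are provided: (a) unpenalized OLS on the selected variables vs
an age-only baseline over 1000 *fresh* splits, with a Gaussian
likelihood-ratio test (statistic n·log(RSS_reduced/RSS_full), χ²
upper-tail p) computed on each training fit — note this comparison is
over-optimistic in absolute terms because the variable set was chosen on
the same underlying data; only the relative a-vs-b contrast is
interpretable; and (b) two-sided permutation tests for marginal
associations (Pearson r, or group mean difference for binary factors)
with the add-one rule p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + N), N = 20 000
by default and exhaustive enumeration used automatically when the exact
null is smaller. RSS is floored at 1e−12 inside log-likelihoods so
noiseless toy inputs stay finite. Raw outcome values (not residuals) are
permuted.

## The synthetic cohort generator

Real cohorts of this kind are available only on request, so the package
generates cohorts with the statistical structure the inference needs:

* 93 predictors in 9 blocks (sociodemographics, anthropometric,
  cardio-metabolic, diabetes-related, lifestyle, medication, sleep,
  laboratory, somatic symptoms), each block an equicorrelated Gaussian
  latent (ρ between 0.25 and 0.7 by block) transformed per variable to
  continuous, log-normal (skewed labs), binary (thresholded at a target
  prevalence) or ordinal (equiprobable level cuts) margins. Transforms
  exercise the dummy-coding and standardization paths downstream.
* Four planted determinants: age (55.4 ± 9.1 y), GFR (90 ± 15), diabetes
  (prevalence 11.9%), diabetes duration (indicator-gated capped
  log-normal, median ≈ 3 y among diabetics). Cross-block latent loadings
  encode that kidney function declines with age (age–GFR latent r = −0.4)
  and diabetes is more prevalent at higher ages (age–diabetes latent
  r = +0.25); the diabetes-block variables (HbA1c, glucose, insulin
  analogues) share a ρ = 0.7 latent, reproducing the collinearity
  challenge the elastic net exists for. Duration's correlation with the
  diabetes indicator (~0.5) arises purely from the zero-inflation
  structure.
* Calibration: the marginal association targets (Pearson r = −0.67 for
  age, +0.37 for GFR, −0.15 for duration; a −0.9 percentage-point outcome
  shift for diabetes, converted to a point-biserial correlation) are
  mapped to direct coefficients by solving β_std = σ_y R⁻¹ t, where R is
  the correlation matrix of the four planted predictors estimated from a
  single large fixed-seed draw (n = 200 000) of the generator's own
  marginals (the thresholded/zero-inflated margins have no convenient
  closed form). Residual noise is set so the total outcome SD is exactly
  1.3 around a mean of 20.5 % ICV; with the loadings above the planted
  effects explain ≈ 48% of outcome variance. A 200-regeneration Monte
  Carlo test verifies each marginal target to ±0.02.
* Missingness is missing-completely-at-random per block (configurable
  rates, outcome never masked); MAR mechanisms are not modelled. A
  `pure_noise` preset keeps the full feature table but plants no effects.

What the generator does **not** emulate: the real joint distribution of
all 93 variables (only block-level collinearity), measurement error,
non-linear or interaction effects, MAR/MNAR missingness, and sampling
designs (no case-control enrichment). Passing tests therefore demonstrate
that the *pipeline* recovers planted structure under realistic
collinearity and noise — not that any particular real-data finding is
correct.

## Imputation and encoding

Missing predictors are completed by a single chained-equations pass
(default 5 cycles): mean/mode initialization, then per-variable
regressions on all other predictors — linear with a Gaussian residual
draw for continuous, ridge-stabilized IRLS logistic with a Bernoulli draw
for binary, linear draw rounded and clipped to observed levels for
ordinal. This is a deliberate single-imputation simplification of
multiple imputation: the resampling pipeline consumes one completed
table, and Rubin's-rules pooling across imputations is out of scope.
Observed cells are never altered; the procedure is deterministic under a
fixed seed. Blocks whose missingness exceeds a threshold (default 0.3)
are dropped before imputation, mirroring the exclusion of
high-missingness questionnaire blocks from primary analyses. Encoding:
continuous and binary columns pass through; a k-level ordinal becomes
k−1 dummies against the lowest level.

## Volumetry

ICV = GM + WM + CSF; ratio correction is 100·volume/ICV, valid for
0 ≤ volume ≤ ICV. Region tables (AAL vocabulary) accept cm³ or mm³ with
an explicit unit column and are normalized internally to cm³. The region
filter keeps regions whose FLAIR-vs-T1 validation Spearman ρ is ≥ 0.597
(inclusive); which regions pass is supplied by the user as a correlation
table, since the underlying validation study's region list is not
redistributed here. A subject whose retained region set is empty gets an
adjusted GMV of 0 with a logged warning rather than an error, keeping
batch runs alive for downstream QC. Image processing (brain extraction,
segmentation, atlas warping) is out of scope.

## Problem sizes and determinism

Default analysis scale is the study scale: n = 293, 93 predictors
(105 encoded columns), 1000 outer splits, 10 inner folds, 100-point λ
grid — a few minutes on one core. The test suite runs reduced but
non-trivial scales (150-split stability runs across three master seeds,
100-split pure-noise runs, 200-split OLS comparisons, 2000-replicate
permutation calibrations). Every random decision descends from explicit
seeds (outer splits from a master `SeedSequence`, per-split inner-CV
folds from the split's own seed), so identical configuration and seeds
reproduce byte-identical artifacts.

## Known limitations

* Selection frequencies are computed on resamples of one fixed cohort:
  a null variable with a lucky sample association in that cohort is
  honestly selected often (see `albumin` in the README example); the
  method ranks within-cohort evidence, it does not certify causality.
* The held-out adjusted R² uses p = selected count, which is undefined
  for very dense models on a 29-subject test set (recorded as NaN and
  excluded from means; ridge sweeps therefore report NaN).
* The elastic-net λ is convention-dependent; compare λ values only
  within this package.
* Logistic/Cox elastic nets, sparse-matrix storage and selective
  inference after selection are not implemented.
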