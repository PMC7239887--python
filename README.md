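# gmvnet

Elastic-net stability selection for ranking determinants of
intracranial-volume-adjusted gray matter volume (GMV) in population
cohorts.

## The problem

Gray matter volume is shaped by many partially collinear factors — age,
kidney function, glycemic status, blood pressure, lifestyle — and with ~90
candidate predictors against ~300 subjects, conventional confounder-adjusted
regression cannot say which of them matter most. `gmvnet` implements the
machine-learning workflow used for this question in population
neuroimaging:

1. **Outcome construction** (`gmvnet.volumetry`): intracranial volume
   ICV = GM + WM + CSF; the outcome is ratio-corrected whole-brain GMV,
   100 · GMV / ICV (% ICV), optionally aggregated from AAL atlas regions
   that pass a validation filter (Spearman ρ ≥ 0.597 agreement between
   FLAIR- and T1-based volumetry).
2. **Elastic net, from scratch** (`gmvnet.elastic_net`): cyclic coordinate
   descent with soft-thresholding on the objective
   (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²),
   plus a descending log-spaced λ path and 10-fold cross-validation.
3. **Stability selection** (`gmvnet.stability`): 1000 random 90/10
   train/test splits (n = 293 → 264 train / 29 test); per split the penalty
   λ is chosen by inner 10-fold CV and the model refitted on the full
   training set; a variable's importance is the number of splits in which
   its coefficient is nonzero. Held-out MSE and adjusted R² are averaged
   over splits and benchmarked against the Null Model (always predicts the
   training mean; its MSE, MSE₀, is the floor any useful model must beat).
4. **Follow-up inference** (`gmvnet.inference`): unpenalized OLS comparison
   of the selected-variable model against an age-only baseline over 1000
   fresh splits with per-split likelihood-ratio tests, and permutation
   tests (20 000 draws, exhaustive where feasible) for marginal
   associations.
5. **Synthetic cohorts** (`gmvnet.synthetic`): the cohort the method was
   designed for is not publicly deposited, so the package ships a
   calibrated generator — 293 subjects, 93 blockwise-correlated mixed-type
   predictors, planted age/GFR/diabetes/diabetes-duration effects whose
   marginal associations match the published ones (r = −0.67, +0.37, a
   −0.9 %-point diabetes shift, r = −0.15), outcome 20.5 ± 1.3 % ICV.

The solver, CV and stability loop are sklearn-style estimators
(`ElasticNetCD`, `CrossValidatedElasticNet`, `StabilitySelector`) that
compose with sklearn pipelines; module functions wrap them.

## Worked example

```python
from gmvnet import kora_like_preset, generate_cohort, encode, StabilitySelector

cohort = generate_cohort(kora_like_preset(), seed=1)
matrix = encode(cohort)            # dummy-codes ordinals -> 105 columns
sel = StabilitySelector(alpha=0.2, n_splits=200, random_state=7).fit(matrix)
print(sel.report_.to_frame().head(5).to_string(index=False))
print(f"EN MSE {sel.mean_test_mse_:.2f} vs null {sel.null_mse_:.2f}")
```

prints

```
         variable  selection_count  selection_frequency  mean_beta
              age              200                1.000  -0.054897
              gfr              200                1.000   0.005297
diabetes_duration              198                0.990  -0.014667
         diabetes              194                0.970  -0.091656
          albumin              113                0.565  -0.064288
EN MSE 1.04 vs null 1.66
```

The four planted determinants head the ranking — age in every split — while
the best null variable (albumin, which merely shares a correlation block
with GFR) trails behind; the elastic net clearly beats the Null Model's
held-out MSE. `mean_beta` is the original-scale coefficient averaged over
the splits where the variable was selected (e.g. −0.055 % ICV per year of
age).

The same pipeline runs from the shell:

```sh
gmvnet run --preset kora_like --n-splits 1000 --seed 1 --out results/
gmvnet simulate --preset kora_like --seed 1 --out cohort.tsv
gmvnet volumetry --regions regions.tsv --compartments comp.tsv \
    --correlations rho.tsv --out gmv.tsv
```

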