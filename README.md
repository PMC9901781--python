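# audimpute

Validated imputation of missing pure-tone audiometric thresholds.

Audiogram datasets pooled across clinics — for example cochlear-implant (CI)
candidacy registries — are riddled with structured missingness: inter-octave
frequencies (750, 1500, 3000, 6000 Hz) are tested far less often than octave
frequencies, so complete-case analysis discards the large majority of
audiograms. Because thresholds at neighbouring frequencies are strongly
correlated, the missing values are highly imputable — but imputation is only
defensible if its error is measured under the missingness structure the data
actually exhibit. `audimpute` is a toolkit for researchers who want to answer,
for their own audiogram table: *which imputation model should I use, and how
many missing thresholds per audiogram can I fill in safely?*

It provides:

* **Data handling** — CSV audiogram tables (one column per frequency in Hz),
  with registry cleaning rules: "no response" → 120 dB, thresholds clipped to
  [0, 120] dB, implausible values removed, blank rows dropped.
* **Sparsity tools** — profiling per-feature missing rates and per-instance
  missing-count histograms; amputation of dense data under controlled
  *quantity* (fixed k per row, or counts mirroring a profiled histogram
  truncated at a cap) and *distribution* (real-world, random, terminal,
  central) of sparsity.
* **Six imputers** behind one scikit-learn `fit`/`transform` contract:
  univariate statistics (UI), per-audiogram interpolation on the octave axis
  (INT: linear / PCHIP / cubic spline), k-nearest-neighbour donor averaging
  with partial distances (KNN), chained-equation penalized regression with
  last-round or SICE output (MICE), per-feature gradient-boosted trees (XGB),
  and a multilayer perceptron on −1-encoded inputs (NN).
* **An assessment engine** — repeated nested cross-validation with per-subset
  sparsity profiling (the data-leakage guard), inner-loop grid search, pooled
  deleted-entry scoring (MAE, RMSE, R²), t confidence intervals across
  simulations, Wilcoxon rank-sum model comparisons, and a safe-imputation-cap
  finder (largest per-row missing count with pooled RMSE < 10 dB, the
  clinically meaningful change threshold).
* **A synthetic generator** emulating registry structure (upward-sloping mean
  profile, powered-exponential correlation over octave distance, 5-dB
  quantization, inter-octave-concentrated missingness), so the whole pipeline
  is testable without any data download.

## The statistics in brief

For deleted entries with true values $y_i$, imputations $f_i$ and pooled mean
$\bar y$:

$$\mathrm{MAE}=\tfrac1n\sum|y_i-f_i|,\qquad
\mathrm{RMSE}=\sqrt{\tfrac1n\sum(y_i-f_i)^2},\qquad
R^2=1-\frac{\sum(y_i-f_i)^2}{\sum(y_i-\bar y)^2}.$$

The MICE engine initializes missing entries with a univariate statistic, then
for $m$ rounds revisits each feature in ascending frequency order and
re-imputes it from all others with an l1- or l2-penalized linear regression
(predictors standardized, so the penalty is scale-free); output is the final
round or the per-entry mean over rounds (SICE). KNN distance between a sparse
query and a donor is the root mean squared difference over shared observed
features; donor values combine with uniform $1/k$ weights or
inverse-distance weights normalized to sum to 1.

Model assessment follows the nested design: per simulation, shuffle and split
into outer folds; per fold, profile sparsity of train and test subsets
independently, reduce each to its complete cases, amputate each dense subset
under the chosen policy (real-world weights from each subset's own profile),
tune hyperparameters by inner-fold grid search on the amputated train subset,
refit, impute the amputated test subset, and pool deleted-entry scores across
folds.

## Worked example

```python
from audimpute import (CVConfig, ImputerSpec, MaskSpec, REDUCED_GRIDS,
                       GeneratorParams, generate_sparse, profile_sparsity,
                       run_nested_cv)

parent = generate_sparse(GeneratorParams(n=20_000, seed=7))
profile = profile_sparsity(parent)
print("missing rate at 1500 Hz:", round(profile.feature_missing_rate[5], 3))

cfg = CVConfig(n_simulations=2, outer_folds=3, inner_folds=2, seed=7)
mask = MaskSpec("real_world", "mirrored", cap=6)
for family in ("MICE", "UI"):
    spec = ImputerSpec(family, grid=REDUCED_GRIDS[family])
    report = run_nested_cv(parent, spec, mask, cfg)
    s = report.summary().set_index("metric")
    print(f"{family:4s} RMSE {s.loc['rmse','mean']:.2f} dB  "
          f"MAE {s.loc['mae','mean']:.2f} dB  R2 {s.loc['r2','mean']:.3f}")
```

prints

```
missing rate at 1500 Hz: 0.731
MICE RMSE 3.51 dB  MAE 2.48 dB  R2 0.981
UI   RMSE 21.51 dB  MAE 17.33 dB  R2 0.300
```

The synthetic parent reproduces the registry's structured missingness
(1500 Hz missing in ~73% of rows). Under real-world-mirrored sparsity capped
at 6 missing features per audiogram, chained-equation imputation fills
deleted thresholds with ~3.5 dB pooled RMSE — far below the 10 dB clinical
threshold — while the univariate baseline, which ignores within-audiogram
correlation, is ~6× worse and explains little variance.

The same machinery is available from the shell:

```sh
audimpute simulate --n 20000 --seed 7 --out-dir data/
audimpute profile --data data/sparse.csv --out-dir reports/
audimpute validate --data data/sparse.csv --models UI,INT,KNN,MICE \
    --quantity mirrored:6 --sims 2 --outer 3 --inner 2 --seed 7 --out-dir out/
```

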