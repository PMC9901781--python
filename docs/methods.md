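# Methods

## Problem setting

A pure-tone audiogram is a vector of hearing thresholds (dB HL) over an
ordered frequency grid; the package defaults to the 11 standard clinical
frequencies 125–8000 Hz. In pooled registries many audiograms are incomplete,
and the missingness is structured: inter-octave frequencies (750, 1500, 3000,
6000 Hz) and 125 Hz are skipped far more often than the octave frequencies.
The package measures, for a given dataset and imputation model, the error
distribution of imputed thresholds under a controlled missingness process,
and from it the largest per-audiogram missing count that can be imputed with
pooled RMSE below a clinically meaningful change (default 10 dB, anchored to
the ±5 dB intra-session test–retest reliability of routine audiometry and to
ototoxicity-monitoring change criteria).

## Cleaning rules

Applied in order, and total (cleaning never fails): "no response" tokens
(configurable, case-insensitive; default NR / No response variants) become
120 dB, the maximum most audiometers record; unrecognized text becomes
missing; numeric values outside a plausibility window (default −20…200 dB)
are removed as invalid rather than clipped; remaining values are clipped into
[0, 120] dB (sites report extremes inconsistently); rows with no observed
threshold are dropped. The two-band rule (remove far outliers, clip near
ones) reconciles "invalid values removed" with "values clipped" in registry
practice. Cleaning is idempotent.

## Amputation model

Sparse test sets with known ground truth are produced by deleting entries
from fully observed (complete-case) data. Two independent axes:

* **Quantity** — either a fixed count k per row, or counts drawn per row from
  a source histogram truncated at a cap and renormalized ("mirrored";
  k = 0 is retained with its source probability, contributing no scored
  entries).
* **Distribution** — per-feature deletion weights: `real_world` (the profiled
  per-feature missing rates, normalized; zero rates floored at 1e-6),
  `random` (uniform), `terminal` (3-fold weight on 125–500 and 4000–8000 Hz),
  `central` (3-fold weight on 750–3000 Hz).

Within a row the k features are chosen by successive weighted draws without
replacement; for k = 1 the per-feature deletion marginal equals the weight
vector exactly, for larger k it only approximates proportionality (documented,
not corrected — the simplest scheme consistent with exact per-row counts).

## Imputer families

All six are scikit-learn-style transformers with two universal contracts:
observed entries pass through untouched, and imputed values are clipped into
[0, 120] dB (clipping is applied uniformly across families). Missing entries
are NaN.

* **UI** — per-feature mean/median/mode (mode ties resolve to the smallest
  value). The baseline every multivariate model must beat.
* **INT** — per-row interpolation through the observed points, with exterior
  gaps extrapolated from the nearest interpolant. The abscissa is log2
  frequency by default (octave steps equidistant, the audiological
  convention; the inter-octave points are *not* midway between their
  neighbours on this axis), with an integer-index axis available for
  sensitivity checks. Methods: linear; PCHIP (monotonicity-preserving,
  continuous first derivative); natural cubic spline (continuous second
  derivative; degenerates to a parabola/line below 4 points). One observed
  point extends as a constant; zero observed points is an error.
* **KNN** — donor averaging over the k training rows nearest in the partial
  (shared-feature mean squared) Euclidean distance, uniform or normalized
  inverse-distance weighted; rows sharing no feature with any donor, or
  features no donor observes, fall back to the training column mean. Backed
  by scikit-learn's nan-Euclidean KNN imputer, whose distance differs from
  the shared-feature RMS distance only by the constant factor sqrt(p), so
  neighbour rankings and normalized weights are identical (verified against a
  brute-force oracle in the tests).
* **MICE** — chained equations: initialize missing entries with a univariate
  statistic; for m rounds visit features in ascending frequency order and
  re-impute each from all others with a penalized linear regression (l1 =
  lasso, l2 = ridge) fitted on the rows where the target is genuinely
  observed. Regressions fitted at training time are replayed round-by-round
  on queries. Output: last round, or per-entry mean over rounds (SICE).
  m = 0 returns the initialization. Used as a point-imputation engine; no
  Rubin's-rules variance pooling.
* **XGB** — one gradient-boosted tree regressor per feature (a multioutput
  wrapper over XGBoost), trained on amputated inputs paired with the dense
  truth; missing inputs ride the trees' native missing-value branches.
* **NN** — one feed-forward MLP (ReLU, Adam) mapping the −1-encoded sparse
  vector to all features at once; −1 sits just below the audiometric floor.
  Zero hidden layers degenerates to ordinary linear regression.

XGB and NN are supervised: they require (sparse input → dense truth) training
pairs, produced by amputating the dense training subset under the same policy
as the test subset.

### Regularization scale in MICE

Predictors are standardized inside each chained regression, making the
penalty strength α scale-free. This matters: on the raw 0–120 dB scale the
Gram matrix has entries of order n·500, so any α ≤ 1 is vacuous — and under
concentrated (real-world, fixed-k) masking, the features that are almost
never observed get regressions fitted on a handful of rows whose
near-unregularized, wild predictions then feed every other feature's
regression, destabilizing the whole chain (pooled RMSE degrades roughly
2–3×). With standardized predictors the default α grid {0.01, 1, 10, 100}
spans negligible-to-strong shrinkage, and the inner search resolves the
trade-off per condition: small α wins when most features are well observed,
α ≈ 10 wins under heavily structured masking.

## Assessment engine

Per simulation: shuffle the sparse parent, split into outer folds (test
subsets disjoint across folds). Per fold: profile the sparsity of the train
and test subsets **independently, after the split** — real-world amputation
weights and mirrored count histograms always come from the subset's own
profile, never from the parent or the other subset (the data-leakage guard);
reduce each subset to complete cases; amputate each dense subset under the
policy; tune hyperparameters by exhaustive grid search with inner k-fold CV
on the amputated train subset (inner splits are amputated afresh from the
train-subset profile, and the same inner masks are shared across candidate
combinations so they face identical problems; objective = RMSE on deleted
entries); refit the winner on the whole amputated train subset; impute the
amputated test subset. Deleted-entry scores pool across all outer folds and
features into one per-simulation MAE/RMSE/R² (R² uses the mean of the pooled
true deleted values — which is why a constant imputer can score below zero);
simulations aggregate as mean ± two-sided Student-t interval (95% for model
tables, 99% conventionally for sweep bands).

Model pairs are compared with the two-sided Wilcoxon rank-sum test on the
per-simulation metric values (unpaired, matching the named test; the sample
unit is the simulation). No multiple-testing correction is applied by
default.

Seed lineage: one root seed per run; per-simulation and per-fold streams are
spawned deterministically, so any cell is independently re-runnable and the
whole pipeline is bit-for-bit reproducible for deterministic models.

Two pragmatic guards, both documented here because the engine, not the
imputers, owns them:

* *Trainable features*: at extreme fixed k with concentrated weights a drawn
  training mask can delete a feature from every row; the engine redraws a few
  times and then restores one random row's entry per emptied feature.
  Test-side masks are never modified.
* *Noise floor*: on real data, pooled MAE materially below the ±5 dB
  test–retest noise (configurable floor, off by default and not applied to
  synthetic data) triggers a leakage warning rather than an error.

The safe-cap finder scans a fixed-k sweep upward and reports the largest k
whose mean RMSE (and that of every smaller evaluated k) stays below the
threshold, 0 if none; by default the k grid must be contiguous from 1, and a
gappy grid is accepted only on request (the answer is then resolved at the
grid's granularity).

The dataset-size sweep subsamples the sparse parent per simulation *before*
profiling, so small datasets also carry noisier sparsity profiles. Restricted
frequency sets (e.g. a 9-frequency analysis dropping 750 and 1500 Hz) are
handled end-to-end by the `frequencies` parameter, not special-cased.

## Synthetic generator

Thresholds are multivariate normal over the log2-frequency axis with
correlation kernel ρ(d) = exp(−(d/ℓ)^γ) in octave distance d, then clipped to
[0, 120] and quantized to 5-dB steps. Defaults:

| parameter | default | rationale |
|---|---|---|
| mean profile | 55…103 dB, upward-sloping | CI candidates hear high frequencies worst; synthetic calibration choice |
| marginal SD | 22 dB | heterogeneous hearing-loss severity; synthetic calibration choice |
| ℓ, γ | 3.66, 1.92 | solved from two registry correlations: ρ ≈ 0.92 at 1 octave (125–250 Hz) and ρ ≈ 0.215 at 4.58 octaves (125–3000 Hz); γ ≤ 2 keeps the kernel positive definite |
| missing rates | 1500 Hz 0.729, 750 Hz 0.654, 125 Hz 0.450, 3000 Hz 0.307, 6000 Hz 0.295, others 0.05 | registry per-feature rates; octave frequencies are commonly tested |
| round step | 5 dB | audiometric convention |

Missingness is independent per entry (MCAR given the rates); rows left blank
are redrawn. Count-matched masking is the amputation module's job, so the
generator stays simple.

**What the emulation does and does not show.** It reproduces the marginal
missing rates, the ≤6-missing concentration, the marginal threshold scale and
the two-point correlation calibration — sufficient to exercise every pipeline
contract and to reproduce the qualitative model ranking (chained equations
best, univariate far worst, errors growing with missing count, safe cap ≈ 6
under real-world weighting). It is exactly linear-Gaussian: it contains no
audiogram shape taxonomy (flat/sloping/corner/notched classes), no
MAR/MNAR missingness, and its within-instance missingness is uncorrelated —
so its complete-case fraction (~2%) is much lower than a real registry's, and
effects that hinge on non-Gaussian shape structure (notably the advantage of
real-world over random deletion placement) do not reproduce on it. Passing
the synthetic suite validates the machinery, not clinical performance on any
particular dataset.

## Scaled problem sizes

The shipped tests and `scripts/acceptance.py` run the engine at 2 simulations
of 3-outer × 2-inner-fold cross-validation with reduced hyperparameter grids,
on a synthetic parent of 70,000 sparse rows (~1,300 complete cases, so
per-fold dense training subsets of ~900 rows — comfortably past the sample
size where the regression-based imputers plateau). The engine's defaults
(10 simulations of 10×10 folds, full grids) match the design a full study
would use.

## Known limitations

* Point imputation only; no imputation-uncertainty propagation.
* Every row is treated as an independent audiogram (no patient/ear linkage).
* Mirrored quantity reproduces the missing-count histogram but not the joint
  pattern of which features co-miss.
* The marginal-proportionality of weighted deletion is exact only at k = 1.
* Air/bone conduction, laterality, and proprietary audiometer formats are out
  of scope.
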