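"""Repeated nested cross-validation assessment of imputation models.

The engine takes a sparse "parent" dataset and, per simulation, shuffles it
and splits it into outer folds.  Within each fold the sparsity profile of the
train and test subsets is measured *independently* (real-world amputation
weights come from each subset's own profile — profiling after the split is
the data-leakage guard), incomplete instances are dropped to form dense
subsets, and each dense subset is amputated under the requested masking
policy so the deleted values are known.  Hyperparameters are tuned by inner
k-fold grid search on the amputated train subset, the winner is refitted on
the whole amputated train subset, and the amputated test subset is imputed.
Deleted-entry scores are pooled across all outer folds into one
per-simulation metric; simulations are aggregated with t confidence
intervals.

On top of the engine sit the four experiments: the quantity × distribution
sweep, model selection with per-instance mirrored sparsity, the dataset-size
sweep, and the safe-imputation-cap finder (largest per-instance missing count
whose pooled RMSE stays below a clinically meaningful threshold, default
10 dB — anchored to audiometric test-retest reliability of ±5 dB).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import AudiogramMatrix, complete_cases
from .imputers import (DEFAULT_GRIDS, grid_combinations, make_imputer,
                       requires_truth)
from .metrics import MetricReport, ScoredEntries, compare_models, rmse, score_all
from .sparsity import (FixedQuantity, MaskPolicy, MirroredQuantity,
                       SparsityProfile, apply_mask, make_weights, profile_sparsity,
                       sample_mask)


class FoldSizeError(ValueError):
    """A fold's dense subset is too small; reduce folds or grow the data."""


@dataclass(frozen=True)
class ImputerSpec:
    """Model family plus fixed hyperparameters and a tuning grid."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    grid: dict | None = None  # None -> DEFAULT_GRIDS[family]

    def combos(self) -> list[dict]:
        grid = DEFAULT_GRIDS[self.family] if self.grid is None else self.grid
        return grid_combinations(grid)


@dataclass(frozen=True)
class MaskSpec:
    """Masking condition: named distribution plus a quantity rule.

    Real-world weights are resolved against each subset's own sparsity
    profile at run time, never against the parent as a whole.
    """

    distribution: str
    quantity: str            # "fixed" or "mirrored"
    k: int | None = None     # for fixed
    cap: int | None = None   # for mirrored

    def realize(self, profile: SparsityProfile) -> MaskPolicy:
        weights = make_weights(self.distribution, profile)
        if self.quantity == "fixed":
            if self.k is None:
                raise ValueError("fixed quantity needs k")
            q = FixedQuantity(self.k)
        elif self.quantity == "mirrored":
            if self.cap is None:
                raise ValueError("mirrored quantity needs cap")
            q = MirroredQuantity(self.cap, profile.count_histogram)
        else:
            raise ValueError(f"unknown quantity rule {self.quantity!r}")
        return MaskPolicy(self.distribution, weights, q)


@dataclass
class CVConfig:
    """Nested-CV study conditions."""

    n_simulations: int = 10
    outer_folds: int = 10
    inner_folds: int = 10
    ci_level: float = 0.95
    seed: int = 0
    safe_rmse_threshold: float = 10.0   # dB; clinically meaningful change
    cap: int = 6
    tuning_metric: str = "rmse"
    #: When set (real-data runs), warn if pooled MAE falls below this floor —
    #: audiometric test-retest noise makes materially lower MAE a leakage sign.
    mae_noise_floor: float | None = None

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Tidy per-condition summary plus the full underlying reports."""

    results: pd.DataFrame
    reports: dict[tuple, MetricReport]
    provenance: dict


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _amputate_training(dense: AudiogramMatrix, policy: MaskPolicy,
                       rng: np.random.Generator, max_tries: int = 5):
    """Amputate a training subset, keeping every feature trainable.

    A model can only learn a feature that retains at least one observed value
    in its amputated training data.  At extreme per-instance missing counts a
    heavily weighted feature can be removed from every row; the mask is
    redrawn a few times and, failing that, repaired by restoring the entry in
    one random row per emptied feature.  Only training-side masks are
    repaired — test-side amputation is never modified.
    """
    mask = sample_mask(dense.values.shape, policy, rng)
    for _ in range(max_tries):
        if not mask.removed.all(axis=0).any():
            break
        mask = sample_mask(dense.values.shape, policy, rng)
    for j in np.flatnonzero(mask.removed.all(axis=0)):
        mask.removed[int(rng.integers(dense.n_instances)), j] = False
    return apply_mask(dense, mask)


def _fit_imputer(spec: ImputerSpec, combo: dict, seed: int,
                 sparse_train: np.ndarray, dense_train: np.ndarray):
    params = {**spec.hyperparameters, **combo}
    imp = make_imputer(spec.family, **params)
    if "random_state" in imp.get_params():
        imp.set_params(random_state=seed)
    if requires_truth(spec.family):
        imp.fit(sparse_train, dense_train)
    else:
        imp.fit(sparse_train)
    return imp


def _score_transform(imp, sparse_test: AudiogramMatrix,
                     truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    completed = imp.transform(sparse_test.values)
    pred = completed[truth["row"].to_numpy(), truth["feature"].to_numpy()]
    return truth["value"].to_numpy(), pred


def _inner_search(spec: ImputerSpec, dense_train: AudiogramMatrix,
                  policy: MaskPolicy, cfg: CVConfig,
                  rng: np.random.Generator, seed: int) -> dict:
    """Grid search by inner k-fold CV on freshly amputated splits.

    Masks are drawn once per split and shared across combos so candidates are
    compared on identical problems.
    """
    combos = spec.combos()
    if len(combos) == 1:
        return combos[0]
    n = dense_train.n_instances
    if n < cfg.inner_folds:
        raise FoldSizeError(
            f"dense train subset has {n} rows for {cfg.inner_folds} inner "
            "folds; reduce folds or enlarge the dataset")
    order = rng.permutation(n)
    splits = np.array_split(order, cfg.inner_folds)
    prepared = []
    for v in range(cfg.inner_folds):
        val_idx = splits[v]
        fit_idx = np.concatenate([splits[u] for u in range(cfg.inner_folds)
                                  if u != v])
        d_fit, d_val = dense_train.take(fit_idx), dense_train.take(val_idx)
        s_fit, _ = _amputate_training(d_fit, policy, rng)
        m_val = sample_mask(d_val.values.shape, policy, rng)
        s_val, truth = apply_mask(d_val, m_val)
        prepared.append((s_fit, d_fit, s_val, truth))
    best_combo, best_score = None, np.inf
    for combo in combos:
        fold_scores = []
        for s_fit, d_fit, s_val, truth in prepared:
            if len(truth) == 0:
                continue
            imp = _fit_imputer(spec, combo, seed, s_fit.values, d_fit.values)
            yt, yp = _score_transform(imp, s_val, truth)
            fold_scores.append(rmse(ScoredEntries(yt, yp)))
        score = float(np.mean(fold_scores)) if fold_scores else np.inf
        if score < best_score:
            best_combo, best_score = combo, score
    return combos[0] if best_combo is None else best_combo


def _run_fold(train_sub: AudiogramMatrix, test_sub: AudiogramMatrix,
              spec: ImputerSpec, mask_spec: MaskSpec, cfg: CVConfig,
              fold_ss: np.random.SeedSequence):
    rng = np.random.default_rng(fold_ss)
    seed = _seed_int(fold_ss)
    # Profiles measured per subset, after the split: the leakage guard.
    train_profile = profile_sparsity(train_sub)
    test_profile = profile_sparsity(test_sub)
    dense_train = complete_cases(train_sub)
    dense_test = complete_cases(test_sub)
    if dense_train.n_instances < max(cfg.inner_folds, 2):
        raise FoldSizeError(
            f"dense train subset has only {dense_train.n_instances} rows; "
            "reduce folds or enlarge the dataset")
    if dense_test.n_instances == 0:
        raise FoldSizeError("dense test subset is empty; enlarge the dataset "
                            "or reduce outer folds")
    train_policy = mask_spec.realize(train_profile)
    test_policy = mask_spec.realize(test_profile)
    best = _inner_search(spec, dense_train, train_policy, cfg, rng, seed)
    # Refit the winner on the whole amputated train subset.
    s_train, _ = _amputate_training(dense_train, train_policy, rng)
    imp = _fit_imputer(spec, best, seed, s_train.values, dense_train.values)
    m_test = sample_mask(dense_test.values.shape, test_policy, rng)
    s_test, truth = apply_mask(dense_test, m_test)
    yt, yp = _score_transform(imp, s_test, truth)
    return yt, yp, best


def _run_simulation(parent: AudiogramMatrix, spec: ImputerSpec,
                    mask_spec: MaskSpec, cfg: CVConfig,
                    sim_ss: np.random.SeedSequence,
                    subsample: int | None = None):
    rng = np.random.default_rng(sim_ss)
    if subsample is not None:
        if subsample > parent.n_instances:
            raise ValueError(f"subsample size {subsample} exceeds the "
                             f"{parent.n_instances} available instances")
        if subsample < cfg.outer_folds:
            raise ValueError(f"subsample size {subsample} is below the "
                             f"{cfg.outer_folds} outer folds")
        parent = parent.take(rng.choice(parent.n_instances, subsample,
                                        replace=False))
    order = rng.permutation(parent.n_instances)
    folds = np.array_split(order, cfg.outer_folds)
    fold_seeds = sim_ss.spawn(cfg.outer_folds)
    yts, yps, chosen = [], [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.concatenate([folds[g] for g in range(cfg.outer_folds)
                                    if g != f])
        yt, yp, best = _run_fold(parent.take(train_idx), parent.take(test_idx),
                                 spec, mask_spec, cfg, fold_seeds[f])
        yts.append(yt)
        yps.append(yp)
        chosen.append(best)
    entries = ScoredEntries(np.concatenate(yts), np.concatenate(yps))
    return entries, chosen


def run_nested_cv(parent: AudiogramMatrix, spec: ImputerSpec,
                  mask_spec: MaskSpec, cfg: CVConfig,
                  subsample: int | None = None) -> MetricReport:
    """Repeated nested CV of one model under one masking condition."""
    root = np.random.SeedSequence(cfg.seed)
    rows, chosen_log = [], []
    for s, sim_ss in enumerate(root.spawn(cfg.n_simulations)):
        entries, chosen = _run_simulation(parent, spec, mask_spec, cfg,
                                          sim_ss, subsample)
        rows.append({"sim": s, **score_all(entries), "n_entries": entries.n})
        chosen_log.append(chosen)
    per_sim = pd.DataFrame(rows)
    if cfg.mae_noise_floor is not None:
        pooled_mae = float(per_sim["mae"].mean())
        if pooled_mae < cfg.mae_noise_floor:
            warnings.warn(
                f"pooled MAE {pooled_mae:.2f} dB is below the "
                f"{cfg.mae_noise_floor} dB test-retest noise floor; "
                "check for data leakage", UserWarning, stacklevel=2)
    provenance = {"seed": cfg.seed, "config": cfg.digest(),
                  "family": spec.family, "mask": asdict(mask_spec),
                  "subsample": subsample,
                  "chosen_hyperparameters": chosen_log}
    return MetricReport(per_sim, cfg.ci_level, provenance)


def _summary_row(report: MetricReport, **keys) -> dict:
    row = dict(keys)
    for _, r in report.summary().iterrows():
        row[f"{r['metric']}_mean"] = r["mean"]
        row[f"{r['metric']}_ci_lo"] = r["ci_lo"]
        row[f"{r['metric']}_ci_hi"] = r["ci_hi"]
    row["n_sims"] = report.n_simulations
    return row


def sweep_quantity_distribution(parent: AudiogramMatrix,
                                specs: list[ImputerSpec],
                                ks, distributions, cfg: CVConfig,
                                ) -> ExperimentResult:
    """Full factorial fixed-k sweep over models × distributions × k."""
    rows, reports = [], {}
    for spec in specs:
        for dist in distributions:
            for k in ks:
                mask_spec = MaskSpec(dist, "fixed", k=int(k))
                rep = run_nested_cv(parent, spec, mask_spec, cfg)
                reports[(spec.family, dist, int(k))] = rep
                rows.append(_summary_row(rep, model=spec.family,
                                         distribution=dist, k=int(k)))
    return ExperimentResult(pd.DataFrame(rows), reports,
                            {"seed": cfg.seed, "config": cfg.digest()})


def select_model(parent: AudiogramMatrix, specs: list[ImputerSpec],
                 distributions, cfg: CVConfig, alpha: float = 0.01,
                 ) -> tuple[ExperimentResult, pd.DataFrame]:
    """Model-selection table with mirrored per-instance sparsity.

    Per-instance missing counts mirror the parent subset's own histogram,
    capped at ``cfg.cap``; every model is run on every distribution, and
    models are compared pairwise per distribution with the Wilcoxon rank-sum
    test on per-simulation values.
    """
    rows, reports, comparisons = [], {}, []
    for dist in distributions:
        mask_spec = MaskSpec(dist, "mirrored", cap=cfg.cap)
        for spec in specs:
            rep = run_nested_cv(parent, spec, mask_spec, cfg)
            reports[(spec.family, dist)] = rep
            rows.append(_summary_row(rep, model=spec.family, distribution=dist))
        for i, a in enumerate(specs):
            for b in specs[i + 1:]:
                for metric in ("mae", "rmse", "r2"):
                    sa = reports[(a.family, dist)].per_sim[metric]
                    sb = reports[(b.family, dist)].per_sim[metric]
                    if len(sa) < 2:
                        continue
                    v = compare_models(sa, sb, alpha)
                    comparisons.append({
                        "distribution": dist, "metric": metric,
                        "model_a": a.family, "model_b": b.family,
                        "p_value": v["p_value"], "verdict": v["verdict"]})
    result = ExperimentResult(pd.DataFrame(rows), reports,
                              {"seed": cfg.seed, "config": cfg.digest(),
                               "alpha": alpha})
    return result, pd.DataFrame(comparisons)


def sweep_dataset_size(parent: AudiogramMatrix, specs: list[ImputerSpec],
                       sizes, cfg: CVConfig,
                       distribution: str = "real_world") -> ExperimentResult:
    """Model performance versus dataset size.

    Per simulation the sparse parent is subsampled without replacement to
    each size *before* the nested-CV machinery, so smaller datasets also
    carry noisier sparsity profiles.
    """
    rows, reports = [], {}
    mask_spec = MaskSpec(distribution, "mirrored", cap=cfg.cap)
    for size in sizes:
        size = int(size)
        if size < cfg.outer_folds:
            raise ValueError(f"size {size} is below outer_folds="
                             f"{cfg.outer_folds}")
        for spec in specs:
            rep = run_nested_cv(parent, spec, mask_spec, cfg, subsample=size)
            reports[(spec.family, size)] = rep
            rows.append(_summary_row(rep, model=spec.family, size=size,
                                     distribution=distribution))
    return ExperimentResult(pd.DataFrame(rows), reports,
                            {"seed": cfg.seed, "config": cfg.digest()})


def find_safe_cap(sweep: ExperimentResult | pd.DataFrame,
                  threshold: float = 10.0,
                  require_contiguous: bool = True) -> pd.DataFrame:
    """Largest safely imputable per-instance missing count per condition.

    Scans k upward and returns the largest k whose mean RMSE (and that of
    every smaller evaluated k) stays below the threshold; 0 when no k is
    safe.  By default the k grid must be contiguous from 1; with
    ``require_contiguous=False`` the scan runs over the evaluated ks only.
    """
    df = sweep.results if isinstance(sweep, ExperimentResult) else sweep
    rows = []
    for (model, dist), grp in df.groupby(["model", "distribution"]):
        grp = grp.sort_values("k")
        ks = grp["k"].to_numpy(dtype=int)
        if require_contiguous and not np.array_equal(
                ks, np.arange(1, len(ks) + 1)):
            raise ValueError(
                f"k grid for ({model}, {dist}) is not contiguous from 1: "
                f"{ks.tolist()}")
        safe = 0
        for k, r in zip(ks, grp["rmse_mean"].to_numpy()):
            if r < threshold:
                safe = int(k)
            else:
                break
        rows.append({"model": model, "distribution": dist,
                     "safe_cap": safe, "threshold": threshold})
    return pd.DataFrame(rows)
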