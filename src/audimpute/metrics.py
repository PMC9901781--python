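"""Scoring imputations on deleted entries and aggregating across simulations.

Metrics are computed only over entries that were deliberately deleted and then
imputed — observed entries never enter a score.  Per-simulation scores pool
all deleted entries across all outer test folds; across-simulation summaries
report the mean with a two-sided Student-t confidence interval.  Model pairs
are compared with the two-sided Wilcoxon rank-sum test on per-simulation
metric values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class EmptyScoreError(ValueError):
    """Raised when a metric is requested on zero scored entries."""


@dataclass(frozen=True)
class ScoredEntries:
    """Paired (true, predicted) values restricted to deleted entries."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self):
        yt = np.asarray(self.y_true, float).ravel()
        yp = np.asarray(self.y_pred, float).ravel()
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have equal length")
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)

    @property
    def n(self) -> int:
        return len(self.y_true)


def _as_scored(s) -> ScoredEntries:
    if not isinstance(s, ScoredEntries):
        s = ScoredEntries(*s)
    if s.n == 0:
        raise EmptyScoreError("no scored entries")
    return s


def mae(s: ScoredEntries) -> float:
    """Mean absolute error, dB."""
    s = _as_scored(s)
    return float(np.mean(np.abs(s.y_true - s.y_pred)))


def rmse(s: ScoredEntries) -> float:
    """Root mean squared error, dB."""
    s = _as_scored(s)
    return float(np.sqrt(np.mean((s.y_true - s.y_pred) ** 2)))


def r2(s: ScoredEntries) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    The reference mean is the mean of the true deleted values in the pooled
    sample, so a constant (univariate) imputer that ignores which entries are
    deleted can score below zero.
    """
    s = _as_scored(s)
    if s.n < 2:
        raise EmptyScoreError("r2 requires at least two scored entries")
    ss_tot = float(np.sum((s.y_true - s.y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroDivisionError("r2 undefined: true values are all identical")
    ss_res = float(np.sum((s.y_true - s.y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def score_all(s: ScoredEntries) -> dict[str, float]:
    return {"mae": mae(s), "rmse": rmse(s), "r2": r2(s)}


def aggregate_simulations(per_sim, level: float = 0.95,
                          ) -> tuple[float, tuple[float, float]]:
    """Mean and two-sided t confidence interval of per-simulation values."""
    x = np.asarray(per_sim, float)
    if len(x) < 2:
        raise ValueError("confidence interval needs at least two simulations")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2, df=len(x) - 1)) * sd / np.sqrt(len(x))
    return m, (m - half, m + half)


@dataclass(frozen=True)
class MetricReport:
    """Across-simulation summary of one model under one masking condition."""

    per_sim: pd.DataFrame        # columns sim, mae, rmse, r2, n_entries
    level: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_simulations(self) -> int:
        return len(self.per_sim)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("mae", "rmse", "r2"):
            vals = self.per_sim[metric].to_numpy()
            if len(vals) >= 2:
                mean, (lo, hi) = aggregate_simulations(vals, self.level)
            else:
                mean, lo, hi = float(vals[0]), np.nan, np.nan
            rows.append({"metric": metric, "mean": mean,
                         "ci_lo": lo, "ci_hi": hi,
                         "level": self.level, "n_sims": len(vals)})
        return pd.DataFrame(rows)

    def mean(self, metric: str = "rmse") -> float:
        return float(self.per_sim[metric].mean())


def compare_models(samples_a, samples_b, alpha: float = 0.01,
                   ) -> dict[str, object]:
    """Wilcoxon rank-sum comparison of two models' per-simulation errors.

    Verdict is ``"a_better"`` iff mean error of a is lower and p < alpha
    (symmetrically for b); ties across both samples are indistinguishable.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"p_value": 1.0, "verdict": "indistinguishable"}
    stat, p = stats.ranksums(a, b)
    p = float(p)
    if p < alpha:
        verdict = "a_better" if a.mean() < b.mean() else "b_better"
    else:
        verdict = "indistinguishable"
    return {"p_value": p, "statistic": float(stat), "verdict": verdict}
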