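"""The six imputation model families behind one fit/transform contract.

Every imputer is a scikit-learn style transformer: ``fit(X, y=None)`` learns
from a (possibly sparse) training matrix, ``transform(X)`` returns a completed
copy of a query matrix.  Missing entries are NaN.  Two contracts hold for all
families: observed entries pass through unchanged, and every imputed value is
clipped into the audiometric range [0, 120] dB.

Families
--------
UI    :class:`UnivariateImputer` — per-feature mean/median/mode.
INT   :class:`InterpolationImputer` — per-instance linear / PCHIP / cubic
      spline along the (log2-)frequency axis, extrapolating with the nearest
      interpolant.
KNN   :class:`KNNThresholdImputer` — donor averaging over the k nearest
      training instances under the mean-over-shared-features Euclidean
      distance, uniform or inverse-distance weighted.
MICE  :class:`ChainedEquationsImputer` — round-robin penalized linear
      regression (l1/l2), with the final round or the mean of all rounds
      (SICE) as output.
XGB   :class:`GradientBoostedImputer` — one gradient-boosted tree regressor
      per feature, trained on sparse inputs paired with known targets.
NN    :class:`NeuralNetImputer` — feed-forward multilayer perceptron on
      -1-encoded inputs predicting all features at once.

The supervised families (XGB, NN) need ground-truth targets: ``fit(X, y)``
with ``X`` the amputated (sparse) matrix and ``y`` the dense matrix it came
from.  The other four ignore ``y``.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator, interp1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer, SimpleImputer
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted
from xgboost import XGBRegressor

from .io import AudiogramMatrix, DEFAULT_FREQUENCIES, THRESHOLD_MAX, THRESHOLD_MIN


class ImputationError(ValueError):
    """Raised when an instance or feature cannot be imputed."""


def _as_array(X) -> np.ndarray:
    if isinstance(X, AudiogramMatrix):
        X = X.values
    return check_array(X, ensure_all_finite="allow-nan", dtype=float, copy=True)


def _check_no_empty_columns(X: np.ndarray, context: str) -> None:
    empty = np.flatnonzero(np.all(np.isnan(X), axis=0))
    if empty.size:
        raise ImputationError(
            f"{context}: training feature(s) {empty.tolist()} have no "
            "observed values")


class BaseAudiogramImputer(TransformerMixin, BaseEstimator):
    """Shared transform contract: fill only missing entries, clip to [0, 120]."""

    def transform(self, X):
        check_is_fitted(self)
        X = _as_array(X)
        miss = np.isnan(X)
        if not miss.any():
            return X
        filled = self._impute(X)
        out = X.copy()
        out[miss] = np.clip(filled[miss], THRESHOLD_MIN, THRESHOLD_MAX)
        return out

    def _impute(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class UnivariateImputer(BaseAudiogramImputer):
    """Fill each feature's missing entries with that feature's own statistic.

    A single-round baseline: the common alternative to complete-case analysis
    and the performance floor every multivariate model is judged against.
    """

    def __init__(self, strategy: str = "mean"):
        self.strategy = strategy

    def fit(self, X, y=None):
        X = _as_array(X)
        if self.strategy not in ("mean", "median", "mode"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        _check_no_empty_columns(X, "univariate imputer")
        sk_strategy = "most_frequent" if self.strategy == "mode" else self.strategy
        self.imputer_ = SimpleImputer(strategy=sk_strategy).fit(X)
        self.statistics_ = self.imputer_.statistics_
        return self

    def _impute(self, X):
        return self.imputer_.transform(X)


class InterpolationImputer(BaseAudiogramImputer):
    """Per-instance interpolation along the frequency axis.

    Uses only the instance's own observed thresholds: interior gaps come from
    the interpolant through the neighbouring observed points, exterior gaps
    from extrapolating the nearest interpolant.  The abscissa is log2
    frequency by default (octave steps equidistant — the audiological
    convention); an integer feature index axis is available for sensitivity
    checks.  PCHIP preserves monotonicity between observed points; the cubic
    spline has continuous second derivatives.  A single observed point
    degenerates to constant extension.
    """

    def __init__(self, method: str = "pchip", x_axis: str = "log2",
                 frequencies=DEFAULT_FREQUENCIES):
        self.method = method
        self.x_axis = x_axis
        self.frequencies = frequencies

    def fit(self, X, y=None):
        if isinstance(X, AudiogramMatrix):
            self.frequencies = X.frequencies
        X = _as_array(X)
        if self.method not in ("linear", "pchip", "cubic_spline"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.x_axis == "log2":
            self.x_ = np.log2(np.asarray(self.frequencies, float))
        elif self.x_axis == "index":
            self.x_ = np.arange(X.shape[1], dtype=float)
        else:
            raise ValueError(f"unknown x_axis {self.x_axis!r}")
        if len(self.x_) != X.shape[1]:
            raise ValueError("frequencies do not match matrix width")
        return self

    def _impute_row(self, row: np.ndarray) -> np.ndarray:
        obs = ~np.isnan(row)
        n_obs = int(obs.sum())
        if n_obs == 0:
            raise ImputationError(
                "instance has no observed thresholds; cannot interpolate")
        out = row.copy()
        if n_obs == 1:
            out[~obs] = row[obs][0]
            return out
        xo, yo = self.x_[obs], row[obs]
        if self.method == "linear":
            f = interp1d(xo, yo, kind="linear", fill_value="extrapolate",
                         assume_sorted=True)
        elif self.method == "pchip":
            f = PchipInterpolator(xo, yo, extrapolate=True)
        else:
            f = CubicSpline(xo, yo)  # not-a-knot; line/parabola below 4 points
        out[~obs] = f(self.x_[~obs])
        return out

    def _impute(self, X):
        out = X.copy()
        for i in range(X.shape[0]):
            if np.isnan(X[i]).any():
                out[i] = self._impute_row(X[i])
        return out


class KNNThresholdImputer(BaseAudiogramImputer):
    """Donor-based imputation from the k most similar training instances.

    Distance between a sparse query and a donor is the root mean squared
    difference over their shared observed features; donors for a missing
    feature must have that feature observed.  Donor values are combined with
    uniform 1/k weights or inverse-distance weights normalized to sum to 1.
    Backed by scikit-learn's nan-Euclidean KNN imputer, whose distance is the
    same up to a constant factor (so rankings and normalized inverse-distance
    weights are identical); a query sharing no feature with any donor falls
    back to the training column mean.
    """

    def __init__(self, n_neighbors: int = 5, weights: str = "uniform"):
        self.n_neighbors = n_neighbors
        self.weights = weights

    def fit(self, X, y=None):
        X = _as_array(X)
        _check_no_empty_columns(X, "knn imputer")
        if self.n_neighbors > X.shape[0]:
            raise ImputationError(
                f"k={self.n_neighbors} exceeds the {X.shape[0]} available donors")
        self.imputer_ = KNNImputer(n_neighbors=self.n_neighbors,
                                   weights=self.weights).fit(X)
        return self

    def _impute(self, X):
        return self.imputer_.transform(X)


class ChainedEquationsImputer(BaseAudiogramImputer):
    """Multiple imputation by chained equations as a point-imputation engine.

    Missing entries are initialized with a univariate statistic, then for
    ``n_rounds`` rounds each feature is visited in ascending frequency order
    and re-imputed by a penalized linear regression of that feature on all
    others (l1 = lasso, l2 = ridge; audiometric features are strongly
    multicollinear, so penalization is essential).  The regressions are fitted
    on the training matrix during ``fit`` and replayed on queries during
    ``transform``.  Output is either the final round's imputation (presumed
    most accurate) or the per-entry mean over all rounds (SICE).

    Predictors are standardized inside each regression, so ``alpha`` (the
    penalty strength, scikit-learn convention) is scale-free rather than tied
    to the 0–120 dB threshold scale; under structured masking some features
    are observed in only a handful of training rows, and meaningful
    regularization there keeps the whole chained system stable.
    ``n_rounds=0`` returns the initialization.
    """

    def __init__(self, estimator: str = "l2", alpha: float = 0.1,
                 n_rounds: int = 10, initial_strategy: str = "mean",
                 output: str = "last_round", random_state: int | None = None):
        self.estimator = estimator
        self.alpha = alpha
        self.n_rounds = n_rounds
        self.initial_strategy = initial_strategy
        self.output = output
        self.random_state = random_state

    def _new_estimator(self):
        if self.estimator == "l2":
            reg = Ridge(alpha=self.alpha)
        elif self.estimator == "l1":
            reg = Lasso(alpha=self.alpha, max_iter=5000)
        else:
            raise ValueError(
                f"estimator must be 'l1' or 'l2', got {self.estimator!r}")
        return make_pipeline(StandardScaler(), reg)

    def _initial_fill(self, X):
        miss = np.isnan(X)
        Xf = X.copy()
        Xf[miss] = np.take(self.initial_statistics_, np.nonzero(miss)[1])
        return Xf, miss

    def fit(self, X, y=None):
        X = _as_array(X)
        if self.output not in ("last_round", "sice_mean"):
            raise ValueError(f"unknown output {self.output!r}")
        if self.initial_strategy not in ("mean", "median"):
            raise ValueError(f"unknown initial_strategy {self.initial_strategy!r}")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        _check_no_empty_columns(X, "chained-equations imputer")
        stat = np.nanmean if self.initial_strategy == "mean" else np.nanmedian
        self.initial_statistics_ = stat(X, axis=0)
        Xf, miss = self._initial_fill(X)
        p = X.shape[1]
        self.round_estimators_ = []
        for _ in range(self.n_rounds):
            round_models = []
            for j in range(p):  # round-robin, ascending frequency order
                obs_j = ~miss[:, j]
                others = np.delete(Xf, j, axis=1)
                est = self._new_estimator()
                est.fit(others[obs_j], X[obs_j, j])
                round_models.append(est)
                if miss[:, j].any():
                    pred = est.predict(others[miss[:, j]])
                    Xf[miss[:, j], j] = np.clip(pred, THRESHOLD_MIN, THRESHOLD_MAX)
            self.round_estimators_.append(round_models)
        return self

    def _impute(self, X):
        Xf, miss = self._initial_fill(X)
        if not self.round_estimators_:
            return Xf
        rounds = np.empty((len(self.round_estimators_), int(miss.sum())))
        for r, round_models in enumerate(self.round_estimators_):
            for j, est in enumerate(round_models):
                if miss[:, j].any():
                    others = np.delete(Xf, j, axis=1)
                    pred = est.predict(others[miss[:, j]])
                    Xf[miss[:, j], j] = np.clip(pred, THRESHOLD_MIN,
                                                THRESHOLD_MAX)
            rounds[r] = Xf[miss]
        if self.output == "sice_mean":
            Xf[miss] = rounds.mean(axis=0)
        return Xf


class GradientBoostedImputer(BaseAudiogramImputer):
    """One gradient-boosted tree regressor per feature (XGBoost).

    Trained on sparse inputs paired with known dense targets — pairs produced
    by amputating a dense training subset under the same masking policy as
    the test data.  Missing inputs are routed by the trees' native
    missing-value branches, so no encoding is needed.
    """

    _requires_truth = True

    def __init__(self, n_estimators: int = 100, max_depth: int = 3,
                 learning_rate: float = 0.1, subsample: float = 1.0,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_array(X)
        if y is None:
            raise ValueError("GradientBoostedImputer needs dense ground-truth "
                             "targets: fit(X_sparse, X_dense)")
        y = _as_array(y)
        if np.isnan(y).any():
            raise ValueError("ground-truth targets must be fully observed")
        base = XGBRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, subsample=self.subsample,
            random_state=0 if self.random_state is None else self.random_state,
            tree_method="hist", n_jobs=1, verbosity=0)
        self.model_ = MultiOutputRegressor(base, n_jobs=1).fit(X, y)
        return self

    def _impute(self, X):
        return np.asarray(self.model_.predict(X), dtype=float)


class NeuralNetImputer(BaseAudiogramImputer):
    """Feed-forward multilayer perceptron on -1-encoded sparse inputs.

    Missing values are denoted with -1 (below the audiometric floor of 0 dB),
    and the network maps the encoded vector to all features at once (ReLU
    activations, Adam optimizer).  ``hidden_layers=0`` degenerates to an
    ordinary linear regression on the encoded inputs.
    """

    _requires_truth = True

    def __init__(self, hidden_layers: int = 1, nodes_per_layer: int = 64,
                 learning_rate: float = 1e-3, max_iter: int = 300,
                 random_state: int | None = None):
        self.hidden_layers = hidden_layers
        self.nodes_per_layer = nodes_per_layer
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _encode(X):
        Xe = X.copy()
        Xe[np.isnan(Xe)] = -1.0
        return Xe

    def fit(self, X, y=None):
        X = _as_array(X)
        if y is None:
            raise ValueError("NeuralNetImputer needs dense ground-truth "
                             "targets: fit(X_sparse, X_dense)")
        y = _as_array(y)
        if np.isnan(y).any():
            raise ValueError("ground-truth targets must be fully observed")
        if self.hidden_layers == 0:
            self.model_ = LinearRegression()
        else:
            self.model_ = MLPRegressor(
                hidden_layer_sizes=(self.nodes_per_layer,) * self.hidden_layers,
                activation="relu", solver="adam",
                learning_rate_init=self.learning_rate,
                max_iter=self.max_iter,
                random_state=0 if self.random_state is None else self.random_state)
        self.model_.fit(self._encode(X), y)
        return self

    def _impute(self, X):
        return np.asarray(self.model_.predict(self._encode(X)), dtype=float)


FAMILIES: dict[str, type[BaseAudiogramImputer]] = {
    "UI": UnivariateImputer,
    "INT": InterpolationImputer,
    "KNN": KNNThresholdImputer,
    "MICE": ChainedEquationsImputer,
    "XGB": GradientBoostedImputer,
    "NN": NeuralNetImputer,
}

#: Full hyperparameter search grids (overridable via config).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "UI": {"strategy": ["mean", "median", "mode"]},
    "INT": {"method": ["linear", "pchip", "cubic_spline"]},
    "KNN": {"n_neighbors": [3, 5, 10, 20, 40],
            "weights": ["uniform", "distance"]},
    "MICE": {"estimator": ["l1", "l2"], "n_rounds": [5, 10, 20],
             "initial_strategy": ["mean", "median"],
             "output": ["last_round", "sice_mean"],
             "alpha": [0.01, 1.0, 10.0, 100.0]},
    "XGB": {"n_estimators": [100, 300], "max_depth": [3, 6],
            "learning_rate": [0.05, 0.1], "subsample": [0.8, 1.0]},
    "NN": {"hidden_layers": [1, 2], "nodes_per_layer": [32, 64, 128],
           "learning_rate": [1e-3, 1e-2]},
}

#: Reduced grids for scaled-down runs (quick benchmarks, smoke experiments).
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "UI": {"strategy": ["mean", "median"]},
    "INT": {"method": ["linear", "pchip"]},
    "KNN": {"n_neighbors": [5, 10], "weights": ["distance"]},
    "MICE": {"estimator": ["l2"], "n_rounds": [10], "alpha": [1.0, 10.0]},
    "XGB": {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1],
            "subsample": [1.0]},
    "NN": {"hidden_layers": [1], "nodes_per_layer": [64],
           "learning_rate": [1e-3]},
}


def make_imputer(family: str, **hyperparameters) -> BaseAudiogramImputer:
    """Instantiate an imputer by family code (UI/INT/KNN/MICE/XGB/NN)."""
    try:
        cls = FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown imputer family {family!r}; "
                         f"choose from {sorted(FAMILIES)}") from None
    return cls(**hyperparameters)


def requires_truth(family: str) -> bool:
    """Whether a family needs dense ground-truth targets at fit time."""
    return getattr(FAMILIES[family], "_requires_truth", False)


def grid_combinations(grid: dict[str, list]) -> list[dict]:
    """Exhaustive list of hyperparameter combinations, deterministic order."""
    if not grid:
        return [{}]
    names = sorted(grid)
    return [dict(zip(names, combo))
            for combo in itertools.product(*(grid[n] for n in names))]
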