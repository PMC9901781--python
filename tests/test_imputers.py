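import numpy as np
import pytest
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import Ridge

from audimpute.imputers import (ChainedEquationsImputer, GradientBoostedImputer,
                                ImputationError, InterpolationImputer,
                                KNNThresholdImputer, NeuralNetImputer,
                                UnivariateImputer, grid_combinations,
                                make_imputer, requires_truth)
from audimpute.synthetic import GeneratorParams, generate_dense

ALL_FAMILIES = ["UI", "INT", "KNN", "MICE", "XGB", "NN"]


def mcar(values, rate, seed):
    rng = np.random.default_rng(seed)
    out = values.copy()
    out[rng.random(out.shape) < rate] = np.nan
    # keep every row and column partly observed for a clean contract test
    for i in np.flatnonzero(np.all(np.isnan(out), axis=1)):
        out[i] = values[i]
    for j in np.flatnonzero(np.all(np.isnan(out), axis=0)):
        out[:, j] = values[:, j]
    return out


@pytest.fixture(scope="module")
def train_query():
    dense = generate_dense(GeneratorParams(n=260, seed=21)).values
    train_d, query_d = dense[:200], dense[200:]
    return (mcar(train_d, 0.2, 1), train_d, mcar(query_d, 0.2, 2), query_d)


def fitted(family, train_s, train_d, **params):
    imp = make_imputer(family, **params)
    if requires_truth(family):
        if "random_state" in imp.get_params():
            imp.set_params(random_state=0)
        imp.fit(train_s, train_d)
    else:
        imp.fit(train_s)
    return imp


class TestSharedContract:
    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_observed_preserved_and_range_respected(self, family, train_query):
        train_s, train_d, query_s, _ = train_query
        out = fitted(family, train_s, train_d).transform(query_s)
        obs = ~np.isnan(query_s)
        np.testing.assert_array_equal(out[obs], query_s[obs])
        assert not np.isnan(out).any()
        assert out.min() >= 0 and out.max() <= 120

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_fully_observed_query_unchanged(self, family, train_query):
        train_s, train_d, _, query_d = train_query
        out = fitted(family, train_s, train_d).transform(query_d)
        np.testing.assert_array_equal(out, query_d)

    @pytest.mark.parametrize("family", ["MICE", "XGB", "NN"])
    def test_deterministic_given_seed(self, family, train_query):
        train_s, train_d, query_s, _ = train_query
        outs = [fitted(family, train_s, train_d).transform(query_s)
                for _ in range(2)]
        np.testing.assert_array_equal(outs[0], outs[1])


class TestUnivariate:
    def test_column_statistics(self):
        train = np.array([[10.0, 0.0], [20.0, 0.0], [30.0, 120.0]])
        query = np.array([[np.nan, np.nan]])
        assert UnivariateImputer("mean").fit(train).transform(query)[0, 0] == 20
        assert UnivariateImputer("mode").fit(train).transform(query)[0, 1] == 0
        assert UnivariateImputer("median").fit(train).transform(query)[0, 0] == 20

    def test_empty_column_rejected(self):
        train = np.array([[10.0, np.nan], [20.0, np.nan]])
        with pytest.raises(ImputationError, match="1"):
            UnivariateImputer().fit(train)


class TestInterpolation:
    def test_linear_matches_closed_form(self, rng):
        """Interior points reproduce the two-point line exactly."""
        x = np.arange(11, dtype=float)
        for _ in range(50):
            row = np.full(11, np.nan)
            i, j = sorted(rng.choice(11, 2, replace=False))
            if j - i < 2:
                continue
            y0, y2 = rng.uniform(20, 100, 2)
            row[i], row[j] = y0, y2
            out = InterpolationImputer("linear", x_axis="index").fit(
                row[None]).transform(row[None])[0]
            interior = np.arange(i + 1, j)
            expected = (y2 - y0) / (x[j] - x[i]) * (x[interior] - x[i]) + y0
            np.testing.assert_allclose(out[interior], expected, atol=1e-9)

    def test_pchip_preserves_monotonicity(self):
        row = np.array([10, np.nan, 30, np.nan, 50, np.nan, 70, np.nan, 90,
                        np.nan, 110], dtype=float)
        out = InterpolationImputer("pchip").fit(row[None]).transform(row[None])[0]
        assert np.all(np.diff(out) >= -1e-12)

    def test_extrapolation_clipped_at_ceiling(self):
        # steep rising line extrapolates past 120 at the top frequencies
        row = np.full(11, np.nan)
        row[0], row[1] = 80.0, 115.0
        out = InterpolationImputer("linear").fit(row[None]).transform(row[None])[0]
        assert out[-1] == 120.0

    def test_single_observed_point_extends_constant(self):
        row = np.full(11, np.nan)
        row[4] = 55.0
        for method in ("linear", "pchip", "cubic_spline"):
            out = InterpolationImputer(method).fit(row[None]).transform(
                row[None])[0]
            np.testing.assert_array_equal(out, np.full(11, 55.0))

    def test_no_observed_point_rejected(self):
        row = np.full((1, 11), np.nan)
        imp = InterpolationImputer("linear").fit(np.full((1, 11), 10.0))
        with pytest.raises(ImputationError):
            imp.transform(row)

    def test_octave_axis_differs_from_index_axis(self):
        # 750 Hz is not midway between 500 and 1000 Hz on the log2 axis
        row = np.full(11, np.nan)
        row[2], row[4] = 40.0, 60.0  # 500 and 1000 Hz
        by_log = InterpolationImputer("linear", x_axis="log2").fit(
            row[None]).transform(row[None])[0][3]
        expected = 40 + 20 * (np.log2(750) - np.log2(500))  # Eq on octave axis
        assert by_log == pytest.approx(expected)


def knn_oracle(train, query, k, weighting):
    """Direct evaluation of partial-distance donor averaging.

    Distance is the root mean squared difference over shared observed
    features; the k nearest donors observing the target feature contribute
    uniformly or with inverse-distance weights normalized to sum to 1; with
    no usable donor the training column mean is used.
    """
    out = query.copy()
    col_means = np.nanmean(train, axis=0)
    for s in range(query.shape[0]):
        for j in np.flatnonzero(np.isnan(query[s])):
            cands, dists = [], []
            for i in range(train.shape[0]):
                if np.isnan(train[i, j]):
                    continue
                shared = ~np.isnan(query[s]) & ~np.isnan(train[i])
                if not shared.any():
                    continue
                d = np.sqrt(np.mean((query[s, shared] - train[i, shared]) ** 2))
                cands.append(train[i, j])
                dists.append(d)
            if not cands:
                out[s, j] = col_means[j]
                continue
            order = np.argsort(dists, kind="stable")[:k]
            vals = np.asarray(cands)[order]
            if weighting == "uniform":
                out[s, j] = vals.mean()
            else:
                w = 1.0 / np.asarray(dists)[order]
                w = w / w.sum()
                assert w.sum() == pytest.approx(1.0)   # Eq: weights sum to 1
                out[s, j] = float(w @ vals)
    return out


class TestKNN:
    def test_hand_example_uniform_and_distance(self):
        # donor j-values {10, 20, 60} at paper-metric distances {1, 1, 2}
        train = np.array([[1.0, 1.0, 10.0],
                          [-1.0, -1.0, 20.0],
                          [2.0, 2.0, 60.0]])
        query = np.array([[0.0, 0.0, np.nan]])
        uni = KNNThresholdImputer(3, "uniform").fit(train).transform(query)
        assert uni[0, 2] == pytest.approx(30.0)
        dist = KNNThresholdImputer(3, "distance").fit(train).transform(query)
        # (10/1 + 20/1 + 60/2) / (1 + 1 + 1/2)
        assert dist[0, 2] == pytest.approx(24.0)

    @pytest.mark.parametrize("weighting", ["uniform", "distance"])
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_brute_force_oracle(self, weighting, k, rng):
        train = rng.uniform(0, 120, (50, 11))
        train[rng.random(train.shape) < 0.25] = np.nan
        train[np.all(np.isnan(train), axis=1), :] = 60.0
        query = rng.uniform(0, 120, (12, 11))
        query[rng.random(query.shape) < 0.3] = np.nan
        query[np.all(np.isnan(query), axis=1), 0] = 60.0
        imp = KNNThresholdImputer(k, weighting).fit(train)
        np.testing.assert_allclose(imp.transform(query),
                                   knn_oracle(train, query, k, weighting),
                                   atol=1e-9)

    def test_identical_donor_copied(self):
        train = np.array([[10.0, 20.0, 30.0], [100.0, 110.0, 120.0]])
        query = np.array([[10.0, 20.0, np.nan]])
        out = KNNThresholdImputer(1, "uniform").fit(train).transform(query)
        assert out[0, 2] == 30.0

    def test_k_exceeding_donors_rejected(self):
        with pytest.raises(ImputationError):
            KNNThresholdImputer(5).fit(np.full((3, 4), 10.0))


class TestChainedEquations:
    def test_collinear_column_recovered(self, rng):
        """With an exactly duplicated feature, the chained regression learns
        the identity map and recovers masked entries almost exactly."""
        a = rng.uniform(20, 100, 80)
        c = rng.uniform(0, 120, 80)
        train = np.column_stack([a, a.copy(), c])
        train[rng.random(80) < 0.2, 1] = np.nan
        query = np.column_stack([a[:20] + 3, a[:20] + 3, c[:20]])
        truth = query[:, 1].copy()
        query[:10, 1] = np.nan
        imp = ChainedEquationsImputer(estimator="l2", alpha=1e-3, n_rounds=5)
        out = imp.fit(train).transform(query)
        assert np.max(np.abs(out[:10, 1] - truth[:10])) <= 0.5

    def test_zero_rounds_returns_initialization(self):
        train = np.array([[10.0, 50.0], [30.0, np.nan], [20.0, 70.0]])
        query = np.array([[np.nan, np.nan]])
        out = ChainedEquationsImputer(n_rounds=0).fit(train).transform(query)
        np.testing.assert_allclose(out[0], [20.0, 60.0])

    def test_sice_mean_averages_rounds(self, train_query):
        train_s, _, query_s, _ = train_query
        last = ChainedEquationsImputer(output="last_round", alpha=1.0,
                                       n_rounds=5).fit(train_s)
        sice = ChainedEquationsImputer(output="sice_mean", alpha=1.0,
                                       n_rounds=5).fit(train_s)
        miss = np.isnan(query_s)
        a, b = last.transform(query_s)[miss], sice.transform(query_s)[miss]
        assert not np.allclose(a, b)
        assert np.abs(a - b).mean() < 5.0  # rounds agree to within a few dB

    def test_cross_check_against_iterative_imputer(self, train_query):
        """Independent route: sklearn's chained-equation imputer with a
        near-unpenalized ridge agrees closely on well-conditioned data."""
        train_s, _, query_s, _ = train_query
        mine = ChainedEquationsImputer(estimator="l2", alpha=1e-6,
                                       n_rounds=10).fit(train_s)
        ref = IterativeImputer(estimator=Ridge(alpha=1e-6), max_iter=10,
                               tol=1e-12, imputation_order="roman",
                               sample_posterior=False,
                               random_state=0).fit(train_s)
        miss = np.isnan(query_s)
        a = mine.transform(query_s)[miss]
        b = np.clip(ref.transform(query_s), 0, 120)[miss]
        assert np.abs(a - b).mean() < 0.5

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            ChainedEquationsImputer(estimator="l3").fit(np.full((5, 3), 1.0))
        with pytest.raises(ValueError):
            ChainedEquationsImputer(output="first").fit(np.full((5, 3), 1.0))


class TestSupervised:
    def test_truth_required(self, train_query):
        train_s, *_ = train_query
        for family in ("XGB", "NN"):
            with pytest.raises(ValueError, match="ground-truth"):
                make_imputer(family).fit(train_s)

    def test_xgb_constant_target(self, rng):
        train_s = rng.uniform(0, 120, (60, 3))
        train_s[rng.random(train_s.shape) < 0.2] = np.nan
        train_d = np.full((60, 3), 50.0)
        query = np.array([[np.nan, 10.0, 20.0]])
        out = GradientBoostedImputer(n_estimators=20).fit(
            train_s, train_d).transform(query)
        assert out[0, 0] == pytest.approx(50.0, abs=1e-3)

    def test_xgb_beats_univariate_on_correlated_data(self):
        dense = generate_dense(GeneratorParams(n=1000, seed=5)).values
        train_d, query_d = dense[:800], dense[800:]
        train_s, query_s = mcar(train_d, 0.3, 3), mcar(query_d, 0.3, 4)
        miss = np.isnan(query_s)
        xgb = GradientBoostedImputer(n_estimators=50, random_state=0).fit(
            train_s, train_d).transform(query_s)
        ui = UnivariateImputer("mean").fit(train_s).transform(query_s)
        err = lambda out: np.sqrt(np.mean((out[miss] - query_d[miss]) ** 2))
        assert err(xgb) < err(ui)

    def test_mlp_beats_univariate_on_correlated_data(self):
        dense = generate_dense(GeneratorParams(n=2000, seed=6)).values
        train_d, query_d = dense[:1600], dense[1600:]
        train_s, query_s = mcar(train_d, 0.3, 5), mcar(query_d, 0.3, 6)
        miss = np.isnan(query_s)
        nn = NeuralNetImputer(hidden_layers=1, nodes_per_layer=64,
                              max_iter=200, random_state=0).fit(
            train_s, train_d).transform(query_s)
        ui = UnivariateImputer("mean").fit(train_s).transform(query_s)
        err = lambda out: np.sqrt(np.mean((out[miss] - query_d[miss]) ** 2))
        assert err(nn) < err(ui)

    def test_zero_hidden_layers_is_linear_model(self, train_query):
        from sklearn.linear_model import LinearRegression
        train_s, train_d, query_s, _ = train_query
        imp = NeuralNetImputer(hidden_layers=0).fit(train_s, train_d)
        assert isinstance(imp.model_, LinearRegression)
        assert not np.isnan(imp.transform(query_s)).any()


def test_grid_combinations_deterministic_and_exhaustive():
    grid = {"b": [1, 2], "a": ["x", "y", "z"]}
    combos = grid_combinations(grid)
    assert len(combos) == 6
    assert combos == grid_combinations(grid)        # stable ordering
    assert grid_combinations({}) == [{}]
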