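import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from wantpred import (
    DegenerateTargetError,
    GreedyForwardRegressor,
    InvalidInputError,
    SelectionResult,
    SingularDesignError,
    adjusted_r2,
    fit_ols,
    percent_error,
    spearman_rho,
    stratified_split,
    train_model,
    validation_error_distribution,
)


# ---------------------------------------------------------------------------
# elementary statistics


class TestFitOls:
    def test_three_point_line(self):
        # normal equations by hand: slope 1.5, intercept 5/6
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        beta = fit_ols(X, [1.0, 2.0, 4.0])
        assert beta[1] == pytest.approx(1.5)
        assert beta[0] == pytest.approx(5 / 6)

    def test_exact_interpolation_has_zero_residual(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = 3.0 - 2.0 * X[:, 1]
        beta = fit_ols(X, y)
        assert np.allclose(beta, [3.0, -2.0])
        assert np.allclose(X @ beta, y)

    def test_uncorrelated_column_gets_zero_slope(self):
        X = np.column_stack([np.ones(4), [1.0, -1.0, 1.0, -1.0]])
        y = np.array([2.0, 2.0, 4.0, 4.0])
        beta = fit_ols(X, y)
        assert beta[0] == pytest.approx(3.0)
        assert beta[1] == pytest.approx(0.0)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(SingularDesignError):
            fit_ols(X, np.arange(5.0))


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert adjusted_r2(y, y, 2) == pytest.approx(1.0)

    def test_mean_prediction_with_one_predictor(self):
        y = np.arange(10.0)
        y_hat = np.full(10, y.mean())
        # R2 = 0 -> 1 - (n-1)/(n-2) = -1/8
        assert adjusted_r2(y, y_hat, 1) == pytest.approx(-1 / 8)

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        y_hat = y + rng.normal(scale=0.5, size=30)
        r2 = 1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2)
        for p in (1, 3, 5):
            assert adjusted_r2(y, y_hat, p) <= r2 + 1e-12

    def test_too_few_rows_raises(self):
        with pytest.raises(InvalidInputError):
            adjusted_r2([1.0, 2.0], [1.0, 2.0], 1)


class TestSpearman:
    def test_monotone_sequences_give_one(self):
        rho, _ = spearman_rho([1, 2, 5, 9], [0.1, 0.5, 0.6, 4.0])
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        a = np.array([3.0, 1.0, 5.0, 2.0])
        rho, _ = spearman_rho(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # sum d^2 = 4 -> 1 - 6*4/(5*24) = 0.8
        rho, p = spearman_rho([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateTargetError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPercentError:
    @pytest.mark.parametrize(
        "real, pred, expected", [(100, 85, 15.0), (200, 230, 15.0), (50, 50, 0.0)]
    )
    def test_scalar(self, real, pred, expected):
        assert percent_error(real, pred) == pytest.approx(expected)

    def test_vector(self):
        out = percent_error([100.0, 200.0], [90.0, 220.0])
        assert np.allclose(out, [10.0, 10.0])

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_error([100.0, 0.0], [90.0, 1.0])


# ---------------------------------------------------------------------------
# splitting


class TestStratifiedSplit:
    @pytest.fixture
    def strat(self):
        rng = np.random.default_rng(0)
        return pd.Series(rng.normal(45, 7, size=93), index=[f"s{i}" for i in range(93)])

    def test_ten_subject_sizes(self):
        vals = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        sp = stratified_split(vals, n_bins=2, seed=1)
        assert (len(sp.calibration_ids), len(sp.test_ids), len(sp.validation_ids)) == (4, 3, 3)

    def test_disjoint_and_exhaustive(self, strat):
        sp = stratified_split(strat, seed=5)
        all_ids = set(sp.calibration_ids) | set(sp.test_ids) | set(sp.validation_ids)
        assert all_ids == set(strat.index)
        assert len(sp.calibration_ids) + len(sp.test_ids) + len(sp.validation_ids) == 93

    def test_sizes_within_rounding(self, strat):
        for seed in range(50):
            sp = stratified_split(strat, seed=seed)
            for ids, frac in zip(
                (sp.calibration_ids, sp.test_ids, sp.validation_ids), (0.4, 0.3, 0.3)
            ):
                assert abs(len(ids) - frac * 93) <= 1

    def test_deterministic(self, strat):
        assert stratified_split(strat, seed=11) == stratified_split(strat, seed=11)

    def test_single_bin_degenerates_to_simple_split(self, strat):
        sp = stratified_split(strat, n_bins=1, seed=2)
        assert len(sp.calibration_ids) + len(sp.test_ids) + len(sp.validation_ids) == 93

    def test_stratification_balances_levels(self, strat):
        # each subset's mean strat value stays near the cohort mean
        sp = stratified_split(strat, seed=3)
        for ids in (sp.calibration_ids, sp.test_ids, sp.validation_ids):
            assert abs(strat[list(ids)].mean() - strat.mean()) < strat.std()

    def test_too_small_cohort_raises(self):
        with pytest.raises(InvalidInputError):
            stratified_split(pd.Series([1.0] * 5), seed=0)


# ---------------------------------------------------------------------------
# the greedy selector


def exhaustive_step(X, y, selected):
    """Independent oracle: scan every remaining candidate and return the one
    whose added least-squares fit minimizes the SSE."""
    n = len(y)
    best_j, best_sse = None, np.inf
    for j in range(X.shape[1]):
        if j in selected:
            continue
        design = np.column_stack([np.ones(n), X[:, selected + [j]]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((y - design @ beta) ** 2))
        if sse < best_sse - 1e-12:
            best_j, best_sse = j, sse
    return best_j


class TestGreedyForwardRegressor:
    def test_planted_pair_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 10))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 2.0 * X[:, 3] - X[:, 7]
        model = GreedyForwardRegressor().fit(X, y)
        assert set(model.selected_idx_) == {3, 7}
        assert model.predict(X) == pytest.approx(y, abs=1e-8)
        assert model.adj_r2_path_[-1] == pytest.approx(1.0)
        # exhaustive best-subset over all pairs agrees
        best_pair, best_sse = None, np.inf
        for pair in itertools.combinations(range(10), 2):
            design = np.column_stack([np.ones(60), X[:, pair]])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = np.sum((y - design @ beta) ** 2)
            if sse < best_sse:
                best_pair, best_sse = pair, sse
        assert set(best_pair) == set(model.selected_idx_)

    def test_first_step_matches_brute_force_scan(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 8))
            y = X @ rng.normal(size=8) + rng.normal(scale=2.0, size=40)
            model = GreedyForwardRegressor().fit(X, y)
            assert model.selected_idx_[0] == exhaustive_step(X, y, [])

    def test_every_step_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 9))
        y = 1.5 * X[:, 0] - X[:, 4] + 0.5 * X[:, 8] + rng.normal(scale=0.3, size=50)
        model = GreedyForwardRegressor().fit(X, y)
        selected = []
        for j in model.selected_idx_:
            assert j == exhaustive_step(X, y, selected)
            selected.append(j)

    def test_calibration_fit_never_degrades(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=60)
        model = GreedyForwardRegressor(min_pct_improvement=0.0).fit(X, y)
        path = model.adj_r2_path_
        r2_path = []  # reconstruct plain R2 from adjusted values
        n = 60
        for k, adj in enumerate(path, start=1):
            r2_path.append(1 - (1 - adj) * (n - k - 1) / (n - 1))
        assert all(b >= a - 1e-12 for a, b in zip(r2_path, r2_path[1:]))

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(DegenerateTargetError):
            GreedyForwardRegressor().fit(X, np.ones(20))

    def test_max_features_cap(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 12))
        y = X @ rng.normal(size=12)
        model = GreedyForwardRegressor(min_pct_improvement=0.0, max_features=4).fit(X, y)
        assert len(model.selected_idx_) <= 4

    def test_deterministic_and_cloneable(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        y = X["b"] * 2 + X["e"] + rng.normal(scale=0.1, size=50)
        m1 = GreedyForwardRegressor().fit(X, y)
        m2 = clone(m1).fit(X, y)
        assert m1.selected_features_ == m2.selected_features_
        assert np.array_equal(m1.coef_, m2.coef_)
        assert m1.get_params() == {"min_pct_improvement": 0.5, "max_features": 10}

    def test_termination_respects_min_improvement(self):
        # second feature is pure noise: relative adj-R2 gain below the
        # threshold must stop selection after the strong feature
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=200)
        noise_feats = rng.normal(size=(200, 5))
        X = np.column_stack([x1, noise_feats])
        y = 3 * x1 + rng.normal(scale=0.05, size=200)
        model = GreedyForwardRegressor(min_pct_improvement=0.5).fit(X, y)
        assert model.selected_idx_ == [0]


# ---------------------------------------------------------------------------
# validation resampling and orchestration


class TestValidationErrorDistribution:
    @pytest.fixture
    def pool(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 500 + 50 * X["x"].to_numpy()
        return X, y

    class _Shifted:
        def __init__(self, factor):
            self.factor = factor

        def predict(self, X):
            return (500 + 50 * X["x"].to_numpy()) * self.factor

    def test_perfect_model_has_zero_error(self, pool):
        X, y = pool
        mean, sd = validation_error_distribution(self._Shifted(1.0), X, y, seed=1)
        assert mean == 0.0 and sd == 0.0

    def test_constant_relative_bias_is_exact(self, pool):
        # a uniform +10% bias gives every subset mean error exactly 10
        X, y = pool
        mean, sd = validation_error_distribution(self._Shifted(1.1), X, y, seed=2)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, pool):
        X, y = pool
        m = self._Shifted(1.03)
        assert validation_error_distribution(m, X, y, seed=9) == validation_error_distribution(
            m, X, y, seed=9
        )

    def test_too_few_reps_rejected(self, pool):
        X, y = pool
        with pytest.raises(InvalidInputError):
            validation_error_distribution(self._Shifted(1.0), X, y, n_reps=1)


class TestTrainModel:
    def test_result_is_internally_consistent(self, default_cohort, pp_series):
        from wantpred import candidate_matrix

        cand = candidate_matrix(default_cohort, 0.85)
        res = train_model(cand, pp_series(default_cohort), outcome="PP", level=0.85, seed=4)
        assert list(res.coefficients) == res.selected_features
        assert len(res.train_adj_r2_path) == len(res.selected_features)
        assert set(res.split["calibration"]).isdisjoint(res.split["validation"])
        assert -1 <= res.validation_spearman[0] <= 1

    def test_json_round_trip_predicts_identically(self, tmp_path, default_cohort, pp_series):
        from wantpred import candidate_matrix

        cand = candidate_matrix(default_cohort, 0.85)
        res = train_model(cand, pp_series(default_cohort), outcome="PP", level=0.85, seed=4)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = SelectionResult.from_json(path)
        assert np.array_equal(back.predict(cand), res.predict(cand))
        assert back.selected_features == res.selected_features
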