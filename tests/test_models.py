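"""Linear/MLP fitting, patient-wise cross-validation, balance testing and
VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest

from robokin import (
    MLPOptions,
    assign_folds,
    fit_linear,
    fit_mlp,
    partition_balance_test,
    patientwise_cv,
    simulate_feature_cohort,
    stratified_evaluation,
    vif,
)
from robokin.models import _r_p_value


class TestFitLinear:
    def test_exact_affine_interpolation(self, rng):
        X = rng.normal(size=(40, 3))
        y = 2.0 + X @ np.array([1.5, -0.5, 3.0])
        fit = fit_linear(X, y)
        assert np.abs(fit.predict(X) - y).max() < 1e-9

    def test_single_feature_slope_intercept(self):
        x = np.linspace(0, 1, 20)[:, None]
        fit = fit_linear(x, 2.0 * x[:, 0] + 1.0)
        assert fit.coef[0] == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(100, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=100)
        fit = fit_linear(X, y)
        resid = y - fit.predict(X)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_noise_coefficients_within_standard_error(self, rng):
        n = 500
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)  # independent of X
        fit = fit_linear(X, y)
        sigma2 = np.sum((y - fit.predict(X)) ** 2) / (n - 3)
        A = np.column_stack([np.ones(n), X])
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(fit.coef) < 3 * se)

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="dep_sum"):
            fit_linear(X, rng.normal(size=30), feature_names=["a", "b", "dep_sum"])


class TestFitMLP:
    def test_recovers_self_realizable_function(self, rng):
        n = 500
        X = rng.uniform(0, 1, (n, 2))
        w1 = np.array([[3.0, -2.0], [1.0, 4.0]])
        b1 = np.array([-1.0, 0.5])
        w2 = np.array([2.0, -1.5])
        y = (1 / (1 + np.exp(-(X @ w1 + b1)))) @ w2 + 0.3
        fit = fit_mlp(X, y, seed=0)
        pred = fit.predict(X)
        r = np.corrcoef(pred, y)[0, 1]
        assert r >= 0.999

    def test_matches_linear_on_linear_data(self, rng):
        n = 200
        X = rng.uniform(0, 1, (n, 1))
        y = 0.8 * X[:, 0] + 0.1
        lin = fit_linear(X, y)
        mlp = fit_mlp(X, y, seed=1)
        r_lin = np.corrcoef(lin.predict(X), y)[0, 1]
        r_mlp = np.corrcoef(mlp.predict(X), y)[0, 1]
        assert r_mlp >= r_lin - 0.01

    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0, 1, (50, 2))
        y = rng.uniform(0, 1, 50)
        f1 = fit_mlp(X, y, seed=42, opts=MLPOptions(restarts=3))
        f2 = fit_mlp(X, y, seed=42, opts=MLPOptions(restarts=3))
        np.testing.assert_array_equal(f1.w1, f2.w1)
        np.testing.assert_array_equal(f1.w2, f2.w2)
        assert f1.b2 == f2.b2

    def test_architecture_two_hidden_units(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        fit = fit_mlp(X, rng.uniform(0, 1, 30), seed=0, opts=MLPOptions(restarts=2))
        assert fit.w1.shape == (3, 2)
        assert fit.b1.shape == (2,)
        assert fit.w2.shape == (2,)


class TestFoldAssignment:
    def test_partition_is_disjoint_and_exhaustive(self):
        patients = [f"P{i}" for i in range(13)]
        for seed in range(200):
            folds = assign_folds(patients, 4, np.random.default_rng(seed))
            assert set(folds) == set(patients)
            sizes = np.bincount(list(folds.values()), minlength=4)
            assert sizes.sum() == 13
            assert sizes.max() - sizes.min() <= 1

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match="patients"):
            assign_folds(["P1", "P2"], 4, np.random.default_rng(0))


class TestPatientwiseCV:
    def test_no_patient_leakage_across_folds(self):
        df = simulate_feature_cohort(20, 3, 0.8, seed=0)
        cv = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=5)
        folds = pd.Series(cv.fold_assignments)
        assert folds.nunique() == 4
        # every row's patient maps to exactly one fold
        assert set(folds.index) == set(df["patient_id"])

    def test_noise_free_affine_target_gives_unit_r(self):
        df = simulate_feature_cohort(16, 2, 0.99, seed=1)
        df["wmft"] = 3.0 * df["x"] - 7.0
        cv = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=2)
        assert cv.mean_r == pytest.approx(1.0, abs=1e-9)
        assert cv.p_value == pytest.approx(0.0, abs=1e-12)

    def test_mean_r_is_average_of_fold_rs(self):
        df = simulate_feature_cohort(20, 3, 0.7, seed=3)
        cv = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=3)
        assert cv.mean_r == pytest.approx(np.mean(cv.per_fold_r), abs=1e-12)
        assert len(cv.per_fold_r) == 4

    def test_small_fold_advises_fewer_folds(self):
        df = simulate_feature_cohort(8, 1, 0.8, seed=0)
        with pytest.raises(ValueError, match="fewer folds"):
            patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=0)

    def test_population_r_recovered(self):
        hits = 0
        for rep in range(10):
            df = simulate_feature_cohort(80, 3, 0.85, seed=600 + rep)
            cv = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=rep)
            hits += abs(cv.mean_r - 0.85) <= 0.05
        assert hits >= 9

    def test_mean_r_improves_as_noise_shrinks(self):
        rs = []
        for pop_r in (0.6, 0.9, 0.99, 0.9999):
            df = simulate_feature_cohort(40, 3, pop_r, seed=11)
            cv = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=11)
            rs.append(cv.mean_r)
        assert all(b > a for a, b in zip(rs, rs[1:]))
        assert rs[-1] > 0.999


class TestStratifiedEvaluation:
    def test_full_range_equals_unrestricted(self):
        df = simulate_feature_cohort(20, 3, 0.8, seed=4)
        full = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=9)
        strat = stratified_evaluation(
            df, ["x"], "wmft", (df["wmft"].min(), df["wmft"].max()), kind="linear",
            k=4, seed=9,
        )
        assert strat.mean_r == pytest.approx(full.mean_r, abs=1e-12)

    def test_disjoint_range_errors(self):
        df = simulate_feature_cohort(20, 3, 0.8, seed=4)
        with pytest.raises(ValueError, match="empty stratum"):
            stratified_evaluation(df, ["x"], "wmft", (1e6, 2e6), kind="linear", seed=0)

    def test_restricted_stratum_lowers_r(self):
        # restricting the target range shrinks target variance, hence R
        df = simulate_feature_cohort(60, 3, 0.9, seed=12)
        full = patientwise_cv(df, ["x"], "wmft", kind="linear", k=4, seed=13)
        lo, hi = df["wmft"].quantile([0.3, 0.7])
        strat = stratified_evaluation(
            df, ["x"], "wmft", (lo, hi), kind="linear", k=4, seed=13
        )
        assert strat.mean_r < full.mean_r


class TestBalanceTest:
    def test_separated_samples(self):
        p = partition_balance_test(np.arange(1, 21), np.arange(100, 121))
        assert p < 0.001

    def test_identical_samples_tie(self):
        with pytest.warns(UserWarning, match="tied"):
            p = partition_balance_test(np.ones(10), np.ones(10))
        assert p == 1.0

    def test_type_one_error_rate_near_nominal(self):
        rng = np.random.default_rng(21)
        flags = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            flags += partition_balance_test(a, b) < 0.05
        assert flags / reps == pytest.approx(0.05, abs=0.02)


class TestVIF:
    def test_orthogonal_features_unit_vif(self):
        n = 64
        base = np.arange(n)
        df = pd.DataFrame(
            {
                "a": np.where(base % 2 == 0, 1.0, -1.0),
                "b": np.where(base % 4 < 2, 1.0, -1.0),
                "c": np.where(base % 8 < 4, 1.0, -1.0),
            }
        )
        rep = vif(df, ["a", "b", "c"])
        for f in ("a", "b", "c"):
            assert rep.vif[f] == pytest.approx(1.0, abs=1e-9)
            assert not rep.flag_high[f]

    def test_duplicated_pair_effectively_infinite(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        rep = vif(df, ["a", "b", "c"])
        assert rep.effectively_infinite["a"]
        assert rep.effectively_infinite["b"]
        assert not rep.effectively_infinite["c"]

    def test_constructed_r_squared_point_nine_gives_vif_ten(self, rng):
        n = 200
        others = rng.normal(size=(n, 2))
        yhat = others @ np.array([1.0, -0.7])
        yhat -= yhat.mean()
        e = rng.normal(size=n)
        A = np.column_stack([np.ones(n), others])
        e -= A @ np.linalg.lstsq(A, e, rcond=None)[0]  # residualize
        e *= np.sqrt((np.sum(yhat**2) / 9.0) / np.sum(e**2))  # R^2 = 0.9
        df = pd.DataFrame(
            {"target_feat": yhat + e, "o1": others[:, 0], "o2": others[:, 1]}
        )
        rep = vif(df, ["target_feat", "o1", "o2"])
        assert rep.r_squared["target_feat"] == pytest.approx(0.9, abs=1e-9)
        assert rep.vif["target_feat"] == pytest.approx(10.0, abs=1e-6)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        n = 150
        X = rng.normal(size=(n, 4))
        X[:, 3] = 0.6 * X[:, 0] + 0.4 * X[:, 1] + 0.3 * rng.normal(size=n)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        rep = vif(df, list(df.columns))
        design = np.column_stack([np.ones(n), X])
        for j, name in enumerate(df.columns):
            oracle = variance_inflation_factor(design, j + 1)
            assert rep.vif[name] == pytest.approx(oracle, rel=1e-8)

    def test_fewer_rows_than_features(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="rows"):
            vif(df, list("abcd"))


class TestRPValue:
    def test_perfect_correlation_p_zero(self):
        assert _r_p_value(1.0, 50) == 0.0

    def test_matches_scipy_pearsonr_p(self, rng):
        from scipy import stats

        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        r, p_ref = stats.pearsonr(x, y)
        assert _r_p_value(r, 60) == pytest.approx(p_ref, rel=1e-9)
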