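"""Diagnostic modelling: screens, LASSO, logistic model, ROC, calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from m6apat import diagnostics as dx


def _binary_frame(x, name="f"):
    return pd.DataFrame([x], index=[name], columns=[f"s{i}" for i in range(len(x))])


class TestUnivariateScreen:
    def test_informative_feature_retained(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["case", "control"], 50)
        x = (y == "case") + rng.normal(0, 0.1, size=100)
        kept, table = dx.univariate_logistic_screen(_binary_frame(x), y)
        assert kept == ["f"]

    def test_constant_feature_rejected(self):
        y = np.repeat(["case", "control"], 10)
        with pytest.raises(ValueError, match="constant"):
            dx.univariate_logistic_screen(_binary_frame(np.ones(20)), y)

    def test_separated_feature_flagged_and_kept(self):
        y = np.repeat(["case", "control"], 20)
        x = np.repeat([2.0, -2.0], 20)
        with pytest.warns(UserWarning, match="separation"):
            kept, table = dx.univariate_logistic_screen(_binary_frame(x), y)
        assert kept == ["f"]
        assert bool(table.loc["f", "separated"])


class TestLassoSolver:
    def test_orthonormal_design_matches_soft_threshold(self):
        rng = np.random.default_rng(1)
        n, p = 64, 6
        q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        x = q * np.sqrt(n)  # X'X/n = I
        y = rng.normal(size=n)
        for lam in (0.02, 0.1, 0.4):
            b = dx.lasso_gaussian_cd(x, y, lam)
            expected = dx.soft_threshold(x.T @ y / n, lam)
            np.testing.assert_allclose(b, expected, atol=1e-6)

    def test_lambda_max_zeroes_every_coefficient(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 10))
        xs = (x - x.mean(0)) / x.std(0)
        y = (rng.random(80) < 0.5).astype(float)
        lmax = dx.lambda_max(xs, y)
        _, coefs = dx._logistic_lasso_path(xs, y, np.array([lmax * 1.0001]))
        np.testing.assert_allclose(coefs[0], 0.0, atol=1e-10)

    def test_matches_reference_l1_logistic_solver(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        n, p = 250, 8
        x = rng.normal(size=(n, p))
        beta = np.array([1.2, -0.7, 0.4] + [0.0] * 5)
        y = (rng.random(n) < 1 / (1 + np.exp(-x @ beta))).astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        lam = 0.05 * dx.lambda_max(xs, y)
        _, coefs = dx._logistic_lasso_path(xs, y, np.array([lam]), tol=1e-9)
        ref = LogisticRegression(
            penalty="l1", C=1.0 / (n * lam), solver="liblinear",
            tol=1e-10, max_iter=5000,
        ).fit(xs, y)
        np.testing.assert_allclose(coefs[0], ref.coef_[0], atol=5e-3)

    def test_nonzero_count_monotone_along_path(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(150, 12))
        beta = np.concatenate([np.ones(4), np.zeros(8)])
        y = (rng.random(150) < 1 / (1 + np.exp(-x @ beta))).astype(float)
        xs = (x - x.mean(0)) / x.std(0)
        lmax = dx.lambda_max(xs, y)
        lams = np.logspace(np.log10(lmax), np.log10(lmax) - 3, 40)
        _, coefs = dx._logistic_lasso_path(xs, y, lams)
        nnz = (np.abs(coefs) > 1e-10).sum(axis=1)
        # allow the occasional drop of a single feature along the path
        assert np.all(np.diff(nnz) >= -1)
        assert nnz[0] <= nnz[-1]

    def test_cv_needs_enough_samples_per_class(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(3, 12)),
                           columns=[f"s{i}" for i in range(12)])
        y = ["case"] * 6 + ["control"] * 6
        with pytest.raises(ValueError, match="10 samples per class"):
            dx.lasso_logistic_cv(mat, y, n_folds=10)

    def test_cv_is_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(8, 60)),
                           index=[f"g{i}" for i in range(8)],
                           columns=[f"s{i}" for i in range(60)])
        mat.iloc[0, :30] += 2.0
        y = ["case"] * 30 + ["control"] * 30
        a = dx.lasso_logistic_cv(mat, y, seed=9)
        b = dx.lasso_logistic_cv(mat, y, seed=9)
        assert a.selected == b.selected
        np.testing.assert_allclose(a.cv_deviance, b.cv_deviance)


class TestMultivariateLogistic:
    def test_two_by_two_odds_ratio(self):
        # cases: 20 exposed, 10 not; controls: 10 exposed, 20 not -> OR = 4
        x = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        y = ["case"] * 30 + ["control"] * 30
        model = dx.fit_multivariate_logistic(_binary_frame(x), y, ["f"])
        or_, lo, hi = model.odds_ratios["f"]
        assert or_ == pytest.approx(4.0, rel=1e-4)
        assert np.exp(model.coefficients["f"]) == pytest.approx(or_, rel=1e-9)
        assert lo < 4.0 < hi

    def test_wald_interval_covers_null_or(self):
        rng = np.random.default_rng(7)
        cover = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=80)
            y = np.where(rng.random(80) < 0.5, "case", "control")
            model = dx.fit_multivariate_logistic(_binary_frame(x), y, ["f"])
            lo, hi = model.odds_ratios["f"][1:]
            cover += lo < 1.0 < hi
        assert cover / n_sim == pytest.approx(0.95, abs=0.035)

    def test_no_features_rejected(self):
        with pytest.raises(ValueError, match="no features"):
            dx.fit_multivariate_logistic(_binary_frame(np.ones(4)), ["case"] * 4, [])

    def test_c_index_equals_auc(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60) + np.repeat([1.0, 0.0], 30)
        y = ["case"] * 30 + ["control"] * 30
        model = dx.fit_multivariate_logistic(_binary_frame(x), y, ["f"])
        assert model.c_index == model.auc.auc


class TestRocAuc:
    def test_perfect_separation_and_constant_scores(self):
        y = np.array([1, 1, 1, 0, 0])
        assert dx.roc_auc([5, 4, 3, 2, 1], y).auc == 1.0
        assert dx.roc_auc([1, 1, 1, 1, 1], y).auc == 0.5

    def test_matches_all_pairs_concordance_oracle(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=60), 1)  # force some ties
        y = np.array([1] * 30 + [0] * 30)
        pos, neg = scores[:30], scores[30:]
        conc = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert dx.roc_auc(scores, y).auc == pytest.approx(conc, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            dx.roc_auc([1, 2], [1, 1])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(int)
        if y.sum() in (0, 30):
            return
        a = dx.roc_auc(scores, y).auc
        b = dx.roc_auc(np.exp(2 * scores), y).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestHosmerLemeshow:
    def test_perfect_binary_predictions_give_zero_statistic(self):
        y = np.array([0] * 30 + [1] * 30, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dx.hosmer_lemeshow(y.copy(), y, g=10)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_rejected_as_zero_df(self):
        p = np.linspace(0.1, 0.9, 20)
        with pytest.raises(ValueError):
            dx.hosmer_lemeshow(p, (p > 0.5).astype(float), g=2)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(10)
        import statsmodels.api as sm

        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(size=300)
            p_true = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
            y = (rng.random(300) < p_true).astype(float)
            fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
            res = dx.hosmer_lemeshow(np.asarray(fit.fittedvalues), y, g=10)
            rejections += res.p_value < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.03)


class TestExternalValidation:
    def test_training_set_reproduces_training_auc(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.normal(size=(3, 80)),
                           index=list("abc"), columns=[f"s{i}" for i in range(80)])
        mat.iloc[0, :40] += 1.0
        y = ["case"] * 40 + ["control"] * 40
        model = dx.fit_multivariate_logistic(mat, y, ["a", "b"])
        assert dx.validate_external(model, mat, y).auc == model.auc.auc

    def test_missing_feature_listed(self):
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(rng.normal(size=(2, 40)),
                           index=["a", "b"], columns=[f"s{i}" for i in range(40)])
        mat.iloc[0, :20] += 1.5
        y = ["case"] * 20 + ["control"] * 20
        model = dx.fit_multivariate_logistic(mat, y, ["a"])
        with pytest.raises(ValueError, match="missing.*a"):
            dx.validate_external(model, mat.drop(index="a"), y)

    def test_label_permutation_drops_auc_to_chance(self):
        rng = np.random.default_rng(13)
        mat = pd.DataFrame(rng.normal(size=(2, 200)),
                           index=["a", "b"], columns=[f"s{i}" for i in range(200)])
        mat.iloc[0, :100] += 2.0
        y = np.array(["case"] * 100 + ["control"] * 100)
        model = dx.fit_multivariate_logistic(mat, y, ["a"])
        aucs = [
            dx.validate_external(model, mat, rng.permutation(y)).auc
            for _ in range(40)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.04)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        mat = pd.DataFrame(rng.normal(size=(2, 60)),
                           index=["a", "b"], columns=[f"s{i}" for i in range(60)])
        mat.iloc[0, :30] += 1.0
        y = ["case"] * 30 + ["control"] * 30
        model = dx.fit_multivariate_logistic(mat, y, ["a", "b"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = dx.DiagnosticModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert dx.validate_external(back, mat, y).auc == model.auc.auc
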