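"""MANOVA / regression / ANOVA / correlation against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from wingmorph.inference import (
    anova_two_factor, manova_two_factor, multivariate_regression_wilks, pearson,
)


def _wilks_determinant_oracle(Y, fa, fb, effect):
    """Brute-force Wilks' lambda via explicit Type III cross-products."""
    Y = np.asarray(Y, float)
    a = np.where(np.asarray(fa, object) == sorted(set(fa))[0], 1.0, -1.0)
    b = np.where(np.asarray(fb, object) == sorted(set(fb))[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(Y)), a, b, a * b])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = (Y - X @ beta).T @ (Y - X @ beta)
    j = {"a": 1, "b": 2, "ab": 3}[effect]
    XtX_inv = np.linalg.inv(X.T @ X)
    H = np.outer(beta[j], beta[j]) / XtX_inv[j, j]
    return np.linalg.det(E) / np.linalg.det(E + H)


def _balanced_design(n_per_cell=8):
    fa, fb = [], []
    for u in ("x", "y"):
        for v in ("p", "q"):
            fa += [u] * n_per_cell
            fb += [v] * n_per_cell
    return fa, fb


class TestManova:
    def test_null_data_gives_lambda_near_one(self):
        rng = np.random.default_rng(5)
        fa, fb = _balanced_design(10)
        Y = rng.normal(size=(40, 3))
        res = manova_two_factor(Y, fa, fb)
        for eff in ("factor_a", "factor_b", "interaction"):
            assert 0.5 < res[eff].statistic <= 1.0
            assert res[eff].p > 0.001

    def test_large_factor_a_shift_detected(self):
        rng = np.random.default_rng(6)
        fa, fb = _balanced_design(10)
        Y = rng.normal(size=(40, 3))
        Y[np.asarray(fa) == "x"] += 5.0
        res = manova_two_factor(Y, fa, fb)
        assert res["factor_a"].statistic < 0.1
        assert res["factor_a"].p < 1e-10
        assert res["interaction"].p > 0.001

    def test_matches_determinant_oracle_small_instance(self):
        rng = np.random.default_rng(7)
        # unbalanced 2x2 to exercise the Type III path
        fa = ["x"] * 9 + ["y"] * 13
        fb = (["p", "q"] * 11)[:22]
        Y = rng.normal(size=(22, 2))
        res = manova_two_factor(Y, fa, fb)
        for eff, key in (("factor_a", "a"), ("factor_b", "b"), ("interaction", "ab")):
            assert res[eff].statistic == pytest.approx(
                _wilks_determinant_oracle(Y, fa, fb, key), abs=1e-10
            )

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(8)
        fa = ["x"] * 11 + ["y"] * 14
        fb = (["p"] * 6 + ["q"] * 7 + ["p"] * 5 + ["q"] * 7)
        Y = rng.normal(size=(25, 3))
        Y[np.asarray(fa) == "x", 0] += 1.0
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["A"], df["B"] = fa, fb
        mv = MANOVA.from_formula(
            "y1 + y2 + y3 ~ C(A, Sum) * C(B, Sum)", data=df
        ).mv_test()
        res = manova_two_factor(Y, fa, fb)
        pairs = [
            ("factor_a", "C(A, Sum)"),
            ("factor_b", "C(B, Sum)"),
            ("interaction", "C(A, Sum):C(B, Sum)"),
        ]
        for mine, theirs in pairs:
            table = mv.results[theirs]["stat"]
            lam = float(table.loc["Wilks' lambda", "Value"])
            p = float(table.loc["Wilks' lambda", "Pr > F"])
            assert res[mine].statistic == pytest.approx(lam, abs=1e-8)
            assert res[mine].p == pytest.approx(p, abs=1e-8)

    def test_too_many_responses_rejected_with_advice(self):
        rng = np.random.default_rng(9)
        fa, fb = _balanced_design(3)
        with pytest.raises(ValueError, match="reduce"):
            manova_two_factor(rng.normal(size=(12, 10)), fa, fb)

    def test_lambda_invariant_to_invertible_response_transform(self):
        rng = np.random.default_rng(10)
        fa, fb = _balanced_design(9)
        Y = rng.normal(size=(36, 4))
        Y[np.asarray(fa) == "x"] += 0.8
        A = rng.normal(size=(4, 4)) + 3 * np.eye(4)
        r1 = manova_two_factor(Y, fa, fb)
        r2 = manova_two_factor(Y @ A, fa, fb)
        for eff in ("factor_a", "factor_b", "interaction"):
            assert r1[eff].statistic == pytest.approx(r2[eff].statistic, rel=1e-8)


class TestMultivariateRegression:
    def test_independent_responses_lambda_near_one(self):
        rng = np.random.default_rng(11)
        lam, F, dfs, p, coef = multivariate_regression_wilks(
            rng.normal(size=(50, 4)), rng.normal(size=50)
        )
        assert lam > 0.7 and p > 0.001

    def test_perfect_linear_relation_lambda_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        direction = np.array([1.0, -2.0, 0.5])
        Y = np.outer(x, direction) + rng.normal(scale=1e-3, size=(40, 3))
        lam, F, dfs, p, coef = multivariate_regression_wilks(Y, x)
        assert lam < 1e-3 and p < 1e-20
        assert np.allclose(coef, direction, atol=1e-3)

    def test_matches_determinant_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 3)) + np.outer(x, [0.5, 0.0, -0.3])
        lam, *_ = multivariate_regression_wilks(Y, x)
        X = np.column_stack([np.ones(30), x])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        E = (Y - X @ beta).T @ (Y - X @ beta)
        Y0 = Y - Y.mean(axis=0)
        H = Y0.T @ Y0 - E  # regression cross-products
        assert lam == pytest.approx(np.linalg.det(E) / np.linalg.det(E + H), abs=1e-10)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="constant"):
            multivariate_regression_wilks(rng.normal(size=(10, 2)), np.ones(10))


class TestAnova:
    def test_identical_values_give_zero_f(self):
        fa, fb = _balanced_design(4)
        res = anova_two_factor(np.full(16, 3.3), fa, fb)
        for eff in ("factor_a", "factor_b", "interaction"):
            assert res[eff].F == 0.0

    def test_factor_a_shift_loads_on_factor_a_only(self):
        rng = np.random.default_rng(15)
        fa, fb = _balanced_design(10)
        y = rng.normal(size=40)
        y[np.asarray(fa) == "x"] += 10.0
        res = anova_two_factor(y, fa, fb)
        assert res["factor_a"].F > 100
        assert res["factor_b"].p > 0.01
        assert res["interaction"].p > 0.01

    def test_matches_statsmodels_type3_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(16)
        # unbalanced cells: 5/9/7/4
        fa = ["x"] * 14 + ["y"] * 11
        fb = ["p"] * 5 + ["q"] * 9 + ["p"] * 7 + ["q"] * 4
        y = rng.normal(size=25) + (np.asarray(fa) == "x") * 0.8
        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        fit = smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=3)
        res = anova_two_factor(y, fa, fb)
        assert res["factor_a"].F == pytest.approx(table.loc["C(A, Sum)", "F"], rel=1e-8)
        assert res["factor_b"].F == pytest.approx(table.loc["C(B, Sum)", "F"], rel=1e-8)
        assert res["interaction"].F == pytest.approx(
            table.loc["C(A, Sum):C(B, Sum)", "F"], rel=1e-8
        )
        assert res["factor_a"].df2 == 25 - 4

    def test_cell_means_and_intervals(self):
        fa = ["x"] * 4 + ["y"] * 4
        fb = ["p", "p", "q", "q"] * 2
        y = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        res = anova_two_factor(y, fa, fb)
        cell = res.cell_means
        row = cell[(cell["factor_a"] == "x") & (cell["factor_b"] == "p")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["ci_low"] < 2.0 < row["ci_high"]

    def test_empty_cell_rejected(self):
        fa = ["x", "x", "y", "y"]
        fb = ["p", "p", "p", "p"]
        with pytest.raises(ValueError):
            anova_two_factor([1.0, 2.0, 3.0, 4.0], fa, fb)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_scipy_on_noise(self):
        import scipy.stats

        rng = np.random.default_rng(17)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, p = pearson(x, y)
        er, ep = scipy.stats.pearsonr(x, y)
        assert (r, p) == (pytest.approx(er), pytest.approx(ep))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson([1.0, 2.0], [3.0, 4.0])
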