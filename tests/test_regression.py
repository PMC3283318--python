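"""OLS fitting, backward elimination, VIF, RCVE and partial correlations.

The independent oracle for OLS is a raw normal-equations solve; VIF is
cross-checked against statsmodels' variance_inflation_factor; partial
correlations are checked against the t-statistic identity.
"""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from utrlen.regression import (
    backward_select,
    fit_ols,
    importance_report,
    partial_correlation,
    rcve,
    vif,
)


def normal_equations(table, predictors, response):
    """Oracle: solve (X'X) b = X'y directly."""
    X = np.column_stack(
        [np.ones(len(table))] + [table[p].to_numpy(float) for p in predictors]
    )
    y = table[response].to_numpy(float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_table(X, y, names=None):
    names = names or [f"x{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["log10_length"] = y
    return df


class TestFitOls:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        table = make_table(x[:, None], 2 + 3 * x)
        res = fit_ols(table, ["x0"])
        assert res.coefficients == pytest.approx([2.0, 3.0])
        assert res.r2 == pytest.approx(1.0)

    def test_five_point_hand_dataset(self):
        table = make_table(
            np.array([[0.0], [1.0], [2.0], [3.0], [4.0]]),
            np.array([1.0, 3.0, 5.0, 7.0, 9.0]),
        )
        res = fit_ols(table, ["x0"])
        assert res.coefficients == pytest.approx([1.0, 2.0], abs=1e-12)

    def test_null_slope_near_zero(self, rng):
        n = 10_000
        table = make_table(rng.standard_normal((n, 1)), rng.standard_normal(n))
        res = fit_ols(table, ["x0"])
        assert abs(res.coefficients[1]) < 0.05
        assert res.r2 < 0.002

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(15, 50))
            p = int(rng.integers(1, 5))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            table = make_table(X, y)
            res = fit_ols(table, list(table.columns[:p]))
            oracle = normal_equations(table, list(table.columns[:p]), "log10_length")
            assert res.coefficients == pytest.approx(oracle, abs=1e-8)

    def test_residual_invariants(self, rng):
        n = 200
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(n)
        table = make_table(X, y)
        res = fit_ols(table, ["x0", "x1", "x2"])
        assert abs(res.residuals.sum()) < 1e-8
        for j in range(3):
            assert abs(res.residuals @ X[:, j]) < 1e-7
        assert res.adjusted_r2 <= res.r2 <= 1.0

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.standard_normal((30, 1))
        table = make_table(np.column_stack([X, 2 * X]), rng.standard_normal(30))
        with pytest.raises(ValueError, match="x1"):
            fit_ols(table, ["x0", "x1"])

    def test_too_few_observations(self, rng):
        table = make_table(rng.standard_normal((3, 2)), np.zeros(3))
        with pytest.raises(ValueError, match="n > p"):
            fit_ols(table, ["x0", "x1"])


class TestBackwardSelect:
    def test_strong_predictors_all_kept(self, rng):
        n = 2000
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, 1.0, 1.0] + rng.standard_normal(n)
        res, trace = backward_select(make_table(X, y), ["x0", "x1", "x2"])
        assert trace.final_predictors == ["x0", "x1", "x2"]
        assert trace.steps == []

    def test_noise_predictor_removed_most_of_the_time(self, rng):
        removed = 0
        runs = 200
        for _ in range(runs):
            n = 400
            X = rng.standard_normal((n, 3))
            y = X[:, 0] + X[:, 1] + 0.5 * rng.standard_normal(n)
            _, trace = backward_select(
                make_table(X, y), ["x0", "x1", "x2"], alpha=0.05
            )
            if "x2" not in trace.final_predictors:
                removed += 1
        assert removed / runs == pytest.approx(0.95, abs=0.04)

    def test_alpha_one_removes_nothing(self, rng):
        X = rng.standard_normal((100, 4))
        y = rng.standard_normal(100)
        _, trace = backward_select(
            make_table(X, y), [f"x{j}" for j in range(4)], alpha=1.0
        )
        assert len(trace.final_predictors) == 4

    def test_alpha_zero_removes_everything(self, rng):
        X = rng.standard_normal((100, 4))
        y = X @ [3.0, 2.0, 1.0, 0.5] + 0.1 * rng.standard_normal(100)
        res, trace = backward_select(
            make_table(X, y), [f"x{j}" for j in range(4)], alpha=0.0
        )
        assert trace.final_predictors == []
        assert res.r2 == 0.0

    def test_trace_records_each_removal(self, rng):
        n = 500
        X = rng.standard_normal((n, 4))
        y = X[:, 0] * 2 + 0.5 * rng.standard_normal(n)
        _, trace = backward_select(
            make_table(X, y), [f"x{j}" for j in range(4)], alpha=0.05
        )
        for step in trace.steps:
            assert step.p_value > 0.05
        assert set(s.removed for s in trace.steps).isdisjoint(
            trace.final_predictors
        )

    def test_aic_criterion_drops_noise_keeps_signal(self, rng):
        n = 1000
        X = rng.standard_normal((n, 3))
        y = X[:, 0] + X[:, 1] + 0.5 * rng.standard_normal(n)
        _, trace = backward_select(
            make_table(X, y), ["x0", "x1", "x2"], criterion="aic"
        )
        assert "x0" in trace.final_predictors
        assert "x1" in trace.final_predictors

    def test_unknown_criterion_rejected(self, rng):
        table = make_table(rng.standard_normal((30, 2)), np.zeros(30))
        with pytest.raises(ValueError, match="criterion"):
            backward_select(table, ["x0", "x1"], criterion="bic")

    def test_near_duplicate_predictors_never_silently_unstable(self, rng):
        x = rng.standard_normal(300)
        table = make_table(
            np.column_stack([x, x + 1e-9 * rng.standard_normal(300)]),
            2 * x + rng.standard_normal(300),
        )
        try:
            _, trace = backward_select(table, ["x0", "x1"], alpha=0.05)
        except ValueError as err:
            assert "collinear" in str(err)
        else:
            assert len(trace.final_predictors) <= 1


class TestVif:
    def test_orthogonal_design_exactly_one(self):
        # +-1 balanced columns: zero-mean, exactly orthogonal
        x0 = np.array([1.0, -1.0, 1.0, -1.0] * 5)
        x1 = np.array([1.0, 1.0, -1.0, -1.0] * 5)
        table = make_table(np.column_stack([x0, x1]), np.zeros(20))
        out = vif(table, ["x0", "x1"])
        assert out["vif"].tolist() == [1.0, 1.0]
        assert not out["flagged"].any()

    def test_near_duplicate_flagged(self, rng):
        x = rng.standard_normal(500)
        table = make_table(
            np.column_stack([x, x + 0.05 * rng.standard_normal(500)]),
            np.zeros(500),
        )
        out = vif(table, ["x0", "x1"])
        assert (out["vif"] > 10).all()
        assert out["flagged"].all()

    def test_exact_duplicate_infinite(self, rng):
        x = rng.standard_normal(100)
        table = make_table(np.column_stack([x, x]), np.zeros(100))
        out = vif(table, ["x0", "x1"])
        assert np.isinf(out["vif"]).all()
        assert out["flagged"].all()

    def test_iid_predictors_near_one(self, rng):
        X = rng.standard_normal((10_000, 4))
        table = make_table(X, np.zeros(10_000))
        out = vif(table, [f"x{j}" for j in range(4)])
        assert out["vif"].max() < 1.01

    def test_matches_statsmodels_oracle(self, rng):
        n, p = 300, 4
        Z = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        names = [f"x{j}" for j in range(p)]
        table = make_table(Z, np.zeros(n))
        ours = vif(table, names)["vif"].to_numpy()
        design = np.column_stack([np.ones(n), Z])
        theirs = [variance_inflation_factor(design, j + 1) for j in range(p)]
        assert ours == pytest.approx(theirs, rel=1e-8)

    def test_invariant_under_affine_rescaling(self, rng):
        n, p = 400, 3
        X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        names = [f"x{j}" for j in range(p)]
        a = vif(make_table(X, np.zeros(n)), names)["vif"].to_numpy()
        X2 = X * np.array([3.0, -0.5, 100.0]) + np.array([1.0, -7.0, 0.1])
        b = vif(make_table(X2, np.zeros(n)), names)["vif"].to_numpy()
        assert a == pytest.approx(b, rel=1e-10)


class TestRcve:
    def test_single_predictor_rcve_is_one(self, rng):
        x = rng.standard_normal(100)
        table = make_table(x[:, None], 2 * x + 0.5 * rng.standard_normal(100))
        assert rcve(table, ["x0"])["x0"] == pytest.approx(1.0)

    def test_null_predictor_near_zero(self, rng):
        n = 5000
        X = rng.standard_normal((n, 2))
        y = 2 * X[:, 0] + rng.standard_normal(n)
        out = rcve(make_table(X, y), ["x0", "x1"])
        assert out["x1"] < 0.005

    def test_matches_brute_force_r2_recomputation(self, rng):
        n = 300
        X = rng.standard_normal((n, 3))
        y = X @ [2.0, 1.0, 0.3] + rng.standard_normal(n)
        table = make_table(X, y)
        names = ["x0", "x1", "x2"]
        out = rcve(table, names)
        assert out.idxmax() == "x0"
        for j, name in enumerate(names):
            r2_full = fit_ols(table, names).r2
            r2_red = fit_ols(table, names[:j] + names[j + 1 :]).r2
            assert out[name] == pytest.approx(
                (r2_full - r2_red) / r2_full, abs=1e-10
            )
            assert r2_red <= r2_full
            assert out[name] >= 0

    def test_zero_r2_is_an_error(self):
        table = make_table(np.array([[1.0], [2.0], [3.0], [4.0]]), np.ones(4))
        with pytest.raises(ValueError, match="RCVE undefined"):
            rcve(table, ["x0"])


class TestPartialCorrelation:
    def test_independent_target_near_zero(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 3))
        y = X[:, 0] + rng.standard_normal(n)
        r = partial_correlation(make_table(X, y), "x2", ["x0", "x1"])
        assert abs(r) < 0.03

    def test_no_others_reduces_to_plain_correlation(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        table = make_table(x[:, None], y)
        r = partial_correlation(table, "x0", [])
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_t_statistic_identity(self, rng):
        n = 400
        X = rng.standard_normal((n, 4)) @ rng.standard_normal((4, 4))
        y = X @ [1.0, -0.5, 0.2, 0.0] + rng.standard_normal(n)
        table = make_table(X, y)
        names = [f"x{j}" for j in range(4)]
        full = fit_ols(table, names)
        for j, name in enumerate(names):
            t = full.t_statistics[j + 1]
            expected = t / np.sqrt(t**2 + full.df_resid)
            r = partial_correlation(table, name, [q for q in names if q != name])
            assert r == pytest.approx(expected, abs=1e-10)

    def test_degenerate_residuals_error(self, rng):
        x = rng.standard_normal(50)
        table = make_table(np.column_stack([x, x * 2.0]), x)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation(table, "x1", ["x0"])


class TestImportanceReport:
    def test_partial_sign_matches_coefficient_sign(self, rng):
        n = 1000
        X = rng.standard_normal((n, 3)) @ rng.standard_normal((3, 3))
        y = X @ [1.0, -1.0, 0.3] + rng.standard_normal(n)
        table = make_table(X, y)
        rep = importance_report(table, ["x0", "x1", "x2"])
        assert (
            np.sign(rep["partial_correlation"]) == np.sign(rep["coefficient"])
        ).all()
        assert (rep["vif"] >= 1).all()
        assert (rep["rcve"] >= 0).all()
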