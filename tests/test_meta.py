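"""Random-intercept REML, partial correlations, Wald tests and BY adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from methclock.errors import DegenerateDesignError
from methclock.meta import (
    MixedModelSpec,
    adjust_family,
    by_adjust,
    compare,
    fit_random_intercept_lmm,
    standardize,
    wald_t,
)
from methclock.synthetic import simulate_score_table


def dense_reml_criterion(theta, y, X, groups):
    """Brute-force REML criterion via full matrices (independent oracle)."""
    codes = pd.factorize(np.asarray(groups))[0]
    Z = np.eye(codes.max() + 1)[codes]
    n, p = X.shape
    V = np.eye(n) + theta * Z @ Z.T
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    rss = r @ Vi @ r
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(A)[1]
            + (n - p) * np.log(rss))


def grid_reml_oracle(y, X, groups):
    """1-D grid search over theta, refined twice (independent oracle)."""
    grid = np.concatenate([[0.0], np.geomspace(1e-6, 1e4, 400)])
    crits = [dense_reml_criterion(t, y, X, groups) for t in grid]
    k = int(np.argmin(crits))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    fine = np.linspace(lo, hi, 2000)
    crits = [dense_reml_criterion(t, y, X, groups) for t in fine]
    theta = fine[int(np.argmin(crits))]
    codes = pd.factorize(np.asarray(groups))[0]
    Z = np.eye(codes.max() + 1)[codes]
    V = np.eye(len(y)) + theta * Z @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return theta, beta


class TestStandardize:
    def test_three_points(self):
        assert standardize([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self, rng):
        z = standardize(rng.normal(5, 3, size=40))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_rejected_with_name(self):
        with pytest.raises(DegenerateDesignError, match="my_var"):
            standardize([2.0, 2.0, 2.0], name="my_var")


class TestREML:
    def test_no_group_variance_reduces_to_ols(self):
        rng = np.random.default_rng(42)
        n = 120
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)  # no group effect at all
        X = np.column_stack([np.ones(n), x])
        groups = np.repeat(np.arange(6), 20)
        fit = fit_random_intercept_lmm(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.tau2 == pytest.approx(0.0, abs=1e-6)
        assert np.abs(fit.beta - ols).max() < 1e-6

    def test_matches_grid_search_oracle_on_balanced_fixture(self):
        # fixed, printed fixture: 2 groups x 6 observations
        y = np.array([1.2, 0.7, 1.9, 1.1, 1.4, 0.8,
                      2.9, 2.2, 3.4, 2.6, 3.1, 2.4])
        x = np.array([0.1, -0.4, 0.9, 0.0, 0.5, -0.2,
                      0.8, 0.2, 1.3, 0.4, 1.0, 0.3])
        X = np.column_stack([np.ones(12), x])
        groups = ["A"] * 6 + ["B"] * 6
        fit = fit_random_intercept_lmm(y, X, groups)
        theta_ref, beta_ref = grid_reml_oracle(y, X, groups)
        assert np.abs(fit.beta - beta_ref).max() < 1e-5
        assert fit.theta == pytest.approx(theta_ref, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n_g, per = 12, 8
        x = rng.normal(size=n_g * per)
        groups = np.repeat(np.arange(n_g), per)
        y = 0.8 * x + rng.normal(0, 0.7, size=n_g)[groups] + rng.normal(size=n_g * per)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_random_intercept_lmm(y, X, groups)
        sm_fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert np.abs(fit.beta - sm_fit.fe_params).max() < 1e-4
        assert fit.tau2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)
        assert fit.sigma2 == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_profile_minimum_by_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        groups = np.repeat(np.arange(6), 10)
        y = x + rng.normal(0, 1.0, size=6)[groups] + rng.normal(size=60)
        X = np.column_stack([np.ones(60), x])
        fit = fit_random_intercept_lmm(y, X, groups)
        assert fit.theta > 0
        c0 = dense_reml_criterion(fit.theta, y, X, groups)
        for eps in (1e-3, 1e-2):
            assert dense_reml_criterion(fit.theta * (1 + eps), y, X, groups) >= c0 - 1e-7
            assert dense_reml_criterion(fit.theta * (1 - eps), y, X, groups) >= c0 - 1e-7

    def test_slope_recovery_small_monte_carlo(self):
        est = []
        for rep in range(25):
            records = simulate_score_table(30, 0.5, 0.3, 0.5, seed=1000 + rep)
            y = np.array([r.adjusted_r2 for r in records])
            logn = np.log([r.subsample_size for r in records])
            z = (logn - logn.mean()) / logn.std(ddof=1)
            X = np.column_stack([np.ones_like(z), z])
            fit = fit_random_intercept_lmm(y, X, [r.gse_id for r in records])
            est.append(fit.beta[1])
        assert abs(np.mean(est) - 0.5) < 0.05

    def test_degenerate_designs_rejected(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateDesignError):
            fit_random_intercept_lmm(y, X, np.repeat([0, 1], 5))
        with pytest.raises(DegenerateDesignError):
            fit_random_intercept_lmm(y, np.ones((10, 1)), np.zeros(10))


class TestWaldT:
    def test_zero_estimate(self):
        t, p = wald_t(0.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_against_numeric_integration_of_t_density(self):
        df = 10

        def density(u):
            c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))
            return c * (1 + u * u / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(density, 2.0, np.inf)
        t, p = wald_t(2.0, 1.0, df)
        assert t == pytest.approx(2.0)
        assert p == pytest.approx(2 * tail, rel=1e-8)

    def test_sign_symmetric(self):
        assert wald_t(1.7, 0.4, 8)[1] == pytest.approx(wald_t(-1.7, 0.4, 8)[1])

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            wald_t(1.0, 0.0, 5)


class TestBYAdjust:
    def test_single_p_unchanged(self):
        assert by_adjust([0.03]) == pytest.approx([0.03])

    def test_two_p_worked_example(self):
        # c(2) = 1.5: 2*1.5*0.01/1 = 0.03, 2*1.5*0.04/2 = 0.06
        assert by_adjust([0.01, 0.04]) == pytest.approx([0.03, 0.06])

    def test_all_equal_closed_form(self):
        m, q = 7, 0.02
        c_m = np.sum(1 / np.arange(1, m + 1))
        assert by_adjust([q] * m) == pytest.approx([min(1.0, q * c_m)] * m)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_dominates_bh_and_monotone(self, ps):
        from statsmodels.stats.multitest import multipletests

        by = by_adjust(ps)
        bh = multipletests(ps, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(by[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])


class TestCompare:
    def test_positive_size_effect_detected(self):
        records = simulate_score_table(30, 0.6, 0.3, 0.5, seed=5)
        res = compare(records, MixedModelSpec("size"))
        assert res.partial_corr > 0.3
        assert res.p_value < 1e-4
        assert res.n_groups == 30

    def test_partial_corr_equals_pearson_without_grouping(self):
        rng = np.random.default_rng(11)
        n = 200
        logn = rng.uniform(3, 8, size=n)
        y = 0.4 * logn + rng.normal(size=n)
        frame = pd.DataFrame({
            "adjusted_r2": y, "rmse": 0.0, "split": "validation", "n": 100,
            "gse_id": [f"G{i % 10}" for i in range(n)], "tissue": "T",
            "penalty": "elastic_net", "sex_config": "joint",
            "validation_sex": "joint",
            "subsample_size": np.exp(logn).round().astype(int),
            "tissue_specific": 1,
        })
        res = compare(frame, MixedModelSpec("size"))
        logn2 = np.log(frame["subsample_size"])
        r = np.corrcoef(logn2, y)[0, 1]
        if res.group_var == 0.0:  # no grouping structure estimated
            assert res.partial_corr == pytest.approx(r, abs=1e-8)
        else:  # still close when the group variance is negligible
            assert res.partial_corr == pytest.approx(r, abs=1e-3)

    def test_null_penalty_contrast_is_null(self):
        pvals = []
        for rep in range(40):
            records = simulate_score_table(20, 0.4, 0.3, 0.5, seed=2000 + rep)
            res = compare(records, MixedModelSpec(
                "penalty", contrast=("elastic_net", "lasso")))
            pvals.append(res.p_value)
        # labels are random: rejections at 5% should be rare
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_missing_contrast_level_rejected(self):
        records = simulate_score_table(5, 0.0, 0.1, 0.5, seed=1)
        frame = pd.DataFrame([r.as_dict() for r in records])
        frame["penalty"] = "lasso"
        with pytest.raises(DegenerateDesignError):
            compare(frame, MixedModelSpec("penalty", contrast=("elastic_net", "lasso")))

    def test_adjust_family_fills_p_by(self):
        records = simulate_score_table(10, 0.5, 0.2, 0.5, seed=3)
        results = [compare(records, MixedModelSpec("size")),
                   compare(records, MixedModelSpec(
                       "penalty", contrast=("elastic_net", "lasso")))]
        adjusted = adjust_family(results)
        assert all(r.p_by is not None and r.p_by >= r.p_value - 1e-15 for r in adjusted)
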