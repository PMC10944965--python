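"""Coordinate-descent elastic net: oracles, invariants and CV behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from methclock.clock import (
    ELASTIC_NET,
    LASSO,
    RIDGE,
    ClockModel,
    PenaltySpec,
    _cd_sweep,
    cross_validate_lambda,
    elastic_net_objective,
    fit_clock,
    fit_path,
    kkt_violation,
    lambda_grid,
    predict_methylage,
)
from methclock.errors import DegenerateDesignError, MissingProbeError

TIGHT = 1e-14  # solver tolerance used when oracle-grade precision is needed


def standardized(X):
    mu, sd = X.mean(0), X.std(0)
    return (X - mu) / sd


def oracle_minimize(Xs, yc, lam, alpha):
    """Independent minimizer of the elastic-net objective via the smooth
    split formulation w = u - v, u,v >= 0 (L-BFGS-B)."""
    n, p = Xs.shape

    def f(z):
        w = z[:p] - z[p:]
        r = yc - Xs @ w
        return (0.5 * r @ r / n + lam * alpha * z.sum()
                + 0.5 * lam * (1 - alpha) * w @ w)

    def grad(z):
        w = z[:p] - z[p:]
        g = -Xs.T @ (yc - Xs @ w) / n + lam * (1 - alpha) * w
        return np.concatenate([g + lam * alpha, -g + lam * alpha])

    res = optimize.minimize(f, np.zeros(2 * p), jac=grad, method="L-BFGS-B",
                            bounds=[(0, None)] * 2 * p,
                            options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 5000})
    return res.x[:p] - res.x[p:]


class TestSolverOracles:
    @pytest.mark.parametrize("alpha,penalty", [(0.0, RIDGE), (0.5, ELASTIC_NET),
                                               (1.0, LASSO)])
    def test_matches_independent_minimizer(self, alpha, penalty, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        Xs, yc = standardized(X), y - y.mean()
        lams = lambda_grid(Xs, yc, alpha, 50)[[5, 25, 45]]
        path = fit_path(X, y, penalty, lambdas=lams, tol=TIGHT)
        for k, lam in enumerate(lams):
            ref = oracle_minimize(Xs, yc, lam, alpha)
            assert np.abs(path.coef_std[k] - ref).max() < 1e-4
            assert elastic_net_objective(Xs, yc, path.coef_std[k], lam, alpha) <= (
                elastic_net_objective(Xs, yc, ref, lam, alpha) + 1e-8)
            assert kkt_violation(Xs, yc, path.coef_std[k], lam, alpha) < 1e-7

    def test_ridge_closed_form(self, rng):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        Xs, yc = standardized(X), y - y.mean()
        lams = np.array([2.0, 0.5, 0.05])
        path = fit_path(X, y, RIDGE, lambdas=lams, tol=1e-18)
        for k, lam in enumerate(lams):
            p = Xs.shape[1]
            ref = np.linalg.solve(Xs.T @ Xs / 30 + lam * np.eye(p), Xs.T @ yc / 30)
            assert np.abs(path.coef_std[k] - ref).max() < 1e-8

    def test_unpenalized_limit_is_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=40)
        lams = np.array([1.0, 0.1, 0.0])
        path = fit_path(X, y, ELASTIC_NET, lambdas=lams, tol=TIGHT)
        Z = np.column_stack([np.ones(40), X])
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        pred_ols = Z @ beta
        pred_cd = path.intercept[2] + X @ path.coef[2]
        assert np.abs(pred_cd - pred_ols).max() < 1e-6

    def test_lasso_lambda_max_zeroes_everything(self, rng):
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=25)
        path = fit_path(X, y, LASSO, nlambda=50)
        assert np.all(path.coef_std[0] == 0.0)
        assert path.intercept[0] == pytest.approx(y.mean())
        # just below lambda_max at least one coefficient activates
        assert np.any(path.coef_std[1] != 0.0)


class TestSolverInvariants:
    def test_objective_decreases_every_sweep(self, rng):
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=30)
        Xs, yc = standardized(X), y - y.mean()
        lam, alpha = 0.3, 0.5
        w = np.zeros(10)
        r = yc.copy()
        prev = elastic_net_objective(Xs, yc, w, lam, alpha)
        for _ in range(50):
            _cd_sweep(np.asfortranarray(Xs), r, w, lam * alpha,
                      1 + lam * (1 - alpha), False)
            cur = elastic_net_objective(Xs, yc, w, lam, alpha)
            assert cur <= prev + 1e-12
            prev = cur

    def test_warm_start_matches_cold_start(self, rng):
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=30)
        Xs, yc = standardized(X), y - y.mean()
        lams = lambda_grid(Xs, yc, 0.5, 20)
        warm = fit_path(X, y, ELASTIC_NET, lambdas=lams, tol=TIGHT)
        thresh = np.sqrt(TIGHT * np.mean(yc**2))
        for k in (5, 12, 19):
            cold = fit_path(X, y, ELASTIC_NET, lambdas=lams[k:k + 1], tol=TIGHT)
            assert np.abs(warm.coef_std[k] - cold.coef_std[0]).max() < 10 * max(thresh, 1e-10)

    def test_kkt_at_scale(self, rng):
        X = rng.normal(size=(80, 40))
        y = X @ np.concatenate([rng.normal(size=5), np.zeros(35)]) + rng.normal(size=80)
        Xs, yc = standardized(X), y - y.mean()
        path = fit_path(X, y, ELASTIC_NET, nlambda=30, tol=1e-16, early_stop=False)
        for k in (0, 10, 29):
            assert kkt_violation(Xs, yc, path.coef_std[k], path.lambdas[k], 0.5) < 1e-7

    def test_zero_variance_probe_dropped(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = 3.14
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="zero-variance"):
            path = fit_path(X, y, LASSO, nlambda=10)
        assert np.all(path.coef[:, 2] == 0.0)

    def test_constant_age_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(DegenerateDesignError):
            fit_path(X, np.full(10, 33.0), LASSO)


class TestCrossValidation:
    def test_loo_below_ten_tenfold_at_ten(self, rng):
        X9 = rng.normal(size=(9, 4))
        y9 = X9 @ np.ones(4) + rng.normal(size=9) * 0.1
        _, path9 = cross_validate_lambda(X9, y9, ELASTIC_NET, seed=0)
        assert path9.cv_n_folds == 9
        X10 = rng.normal(size=(10, 4))
        y10 = X10 @ np.ones(4) + rng.normal(size=10) * 0.1
        _, path10 = cross_validate_lambda(X10, y10, ELASTIC_NET, seed=0)
        assert path10.cv_n_folds == 10

    def test_selected_lambda_minimizes_cv_curve(self, rng):
        X = rng.normal(size=(50, 3))
        y = X @ np.array([2.0, -1.0, 0.5])  # noiseless exact linear signal
        lam, path = cross_validate_lambda(X, y, ELASTIC_NET, seed=1)
        k = int(np.where(path.lambdas == lam)[0][0])
        assert path.cv_mse[k] == path.cv_mse.min()
        assert path.cv_mse[k] <= path.cv_mse[0]

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(2, 3))
        with pytest.raises(DegenerateDesignError):
            cross_validate_lambda(X, np.array([1.0, 2.0]), LASSO)


class TestFitClockAndPredict:
    def _noiseless_frame(self, rng, n=30, p=6):
        ages = rng.uniform(25, 80, size=n)
        slopes = rng.uniform(0.01, 0.05, size=p)
        M = slopes[:, None] * ages[None, :] + rng.normal(0, 0.0, size=(p, n))
        frame = pd.DataFrame(M, index=[f"cg{j}" for j in range(p)],
                             columns=[f"S{i}" for i in range(n)])
        return frame, ages

    def test_noiseless_training_fit_is_exact(self, rng):
        frame, ages = self._noiseless_frame(rng)
        model = fit_clock(frame, ages, ELASTIC_NET, seed=0)
        pred = predict_methylage(model, frame).to_numpy()
        resid = pred - ages
        # the calibration regression absorbs residual shrinkage; the fit
        # itself must be essentially perfect
        assert np.corrcoef(pred, ages)[0, 1] > 1 - 1e-6

    def test_same_seed_identical_model(self, rng):
        frame, ages = self._noiseless_frame(rng)
        frame += rng.normal(0, 0.3, size=frame.shape)
        m1 = fit_clock(frame, ages, LASSO, seed=11)
        m2 = fit_clock(frame, ages, LASSO, seed=11)
        assert m1.coefficients == m2.coefficients
        assert m1.intercept == m2.intercept
        assert m1.lambda_selected == m2.lambda_selected

    def test_predict_arithmetic(self):
        model = ClockModel(intercept=10.0, coefficients={"cgA": 2.0},
                           penalty=LASSO, lambda_selected=0.1)
        M = pd.DataFrame({"s1": [1.5, 9.9]}, index=["cgA", "cgOther"])
        assert predict_methylage(model, M).iloc[0] == pytest.approx(13.0)

    def test_predict_all_zero_model_is_intercept(self):
        model = ClockModel(intercept=47.0, coefficients={}, penalty=RIDGE,
                           lambda_selected=1.0)
        M = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"],
                         columns=["s1", "s2", "s3"])
        assert (predict_methylage(model, M) == 47.0).all()

    def test_predict_missing_probe_raises_with_ids(self):
        model = ClockModel(intercept=0.0, coefficients={"cgZ": 1.0},
                           penalty=LASSO, lambda_selected=0.1)
        M = pd.DataFrame({"s1": [0.5]}, index=["cgA"])
        with pytest.raises(MissingProbeError, match="cgZ"):
            predict_methylage(model, M)


def test_penalty_spec_alpha_consistency():
    assert PenaltySpec.from_name("elnet") == ELASTIC_NET
    with pytest.raises(ValueError):
        PenaltySpec(name="ridge", alpha=0.5)
    with pytest.raises(ValueError):
        PenaltySpec(name="bridge", alpha=0.5)
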