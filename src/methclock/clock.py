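"""Penalized linear regression of age on M-values.

A methylation age clock is the minimizer, over intercept b0 and weights w, of

    (1/(2n)) * sum_i (age_i - b0 - m_i' w)^2  +  lam * P_alpha(w),
    P_alpha(w) = alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2,

with predictors internally standardized (mean 0, SD 1, population
denominator) so the penalty acts on the standardized scale, and coefficients
reported back on the original M-value scale. alpha = 0 is ridge, 1 is lasso,
0.5 the equally-weighted elastic net. The problem is solved by cyclic
coordinate descent with warm starts along a decreasing 50-point lambda grid,
and the penalty strength is chosen by internal cross-validation (10-fold for
n >= 10, leave-one-out below) minimizing held-out mean squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .errors import DegenerateDesignError, MissingProbeError

NLAMBDA_DEFAULT = 50
TOL_DEFAULT = 1e-7
MAX_SWEEPS = 100_000
#: early path termination (matching the reference solver's defaults): stop
#: once the training deviance ratio exceeds PATH_DEVMAX or gains less than
#: PATH_FDEV (fractionally) per lambda step
PATH_FDEV = 1e-5
PATH_DEVMAX = 0.999
#: surrogate L1 weight used only to build the lambda grid when alpha == 0
RIDGE_GRID_ALPHA = 1e-3

_PENALTY_ALPHAS = {"ridge": 0.0, "lasso": 1.0, "elastic_net": 0.5}


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with its fixed L1 mixing weight alpha."""

    name: str
    alpha: float

    def __post_init__(self):
        if self.name not in _PENALTY_ALPHAS:
            raise ValueError(f"unknown penalty {self.name!r}")
        if not np.isclose(self.alpha, _PENALTY_ALPHAS[self.name]):
            raise ValueError(
                f"alpha {self.alpha} inconsistent with penalty {self.name!r}"
            )

    @classmethod
    def from_name(cls, name: str) -> "PenaltySpec":
        aliases = {"elnet": "elastic_net", "elasticnet": "elastic_net"}
        name = aliases.get(name, name)
        return cls(name=name, alpha=_PENALTY_ALPHAS[name])


RIDGE = PenaltySpec.from_name("ridge")
LASSO = PenaltySpec.from_name("lasso")
ELASTIC_NET = PenaltySpec.from_name("elastic_net")


@dataclass
class RegularizationPath:
    """Solutions along a decreasing lambda grid.

    ``coef_std`` holds standardized-scale weights (nlambda x p); ``coef``
    and ``intercept`` are the equivalent original-scale model per lambda.
    ``cv_mse``/``cv_se`` are filled by cross-validation.
    """

    lambdas: np.ndarray
    coef_std: np.ndarray
    coef: np.ndarray
    intercept: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    alpha: float
    cv_mse: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    cv_n_folds: int | None = None

    def predict(self, X: np.ndarray, k: int) -> np.ndarray:
        """Predict ages with the model at lambda index ``k``."""
        return self.intercept[k] + np.asarray(X, dtype=float) @ self.coef[k]


@dataclass
class ClockModel:
    """A trained clock: intercept (years) plus sparse CpG weights
    (years per M-unit) with full training provenance."""

    intercept: float
    coefficients: dict[str, float]
    penalty: PenaltySpec
    lambda_selected: float
    tissue: str = ""
    sex_config: str = "joint"
    n_train: int = 0
    training_gse_ids: tuple[str, ...] = ()
    subsample_size: int = 0
    seed: int = 0
    #: standardized-scale weights (same keys); not serialized
    coefficients_std: dict[str, float] = field(default_factory=dict)

    def nonzero_cpgs(self) -> set[str]:
        return {k for k, v in self.coefficients.items() if v != 0.0}


# ---------------------------------------------------------------------------
# coordinate-descent kernel


@njit(cache=True, fastmath=True)
def _cd_sweep(X, r, w, lam_l1, denom, active_only):  # pragma: no cover
    """One cyclic coordinate-descent sweep in place; returns the largest
    coefficient change.

    X is Fortran-ordered standardized n x p with unit column mean-square,
    so each update is the exact 1-D minimizer:
        w_j <- S(w_j + x_j'r/n, lam*alpha) / (1 + lam*(1-alpha)).
    ``r`` is maintained as the current residual y - Xw.
    """
    n, p = X.shape
    max_delta = 0.0
    for j in range(p):
        wj = w[j]
        if active_only and wj == 0.0:
            continue
        dot = 0.0
        for i in range(n):
            dot += X[i, j] * r[i]
        rho = wj + dot / n
        if rho > lam_l1:
            wn = (rho - lam_l1) / denom
        elif rho < -lam_l1:
            wn = (rho + lam_l1) / denom
        else:
            wn = 0.0
        d = wn - wj
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            w[j] = wn
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True, fastmath=True)
def _cd_sweep_gram(G, g, w, lam_l1, denom, active_only):  # pragma: no cover
    """Gram-form sweep: ``g`` holds the current gradient c - G w (with
    G = X'X/n, c = X'y/n), so each coordinate update costs O(p) regardless
    of n. Used when the Gram matrix is cheaper than residual updates."""
    p = w.shape[0]
    max_delta = 0.0
    for j in range(p):
        wj = w[j]
        if active_only and wj == 0.0:
            continue
        rho = wj + g[j]
        if rho > lam_l1:
            wn = (rho - lam_l1) / denom
        elif rho < -lam_l1:
            wn = (rho + lam_l1) / denom
        else:
            wn = 0.0
        d = wn - wj
        if d != 0.0:
            for k in range(p):
                g[k] -= d * G[k, j]
            w[j] = wn
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True, fastmath=True)
def _cd_path_kernel(X, y, lambdas, alpha, thresh, max_sweeps, use_gram,
                    fdev, devmax):  # pragma: no cover
    """Warm-started path: at each lambda, converge on the active set, then
    run a full sweep to admit new actives; converged when a full sweep moves
    no coefficient by ``thresh`` or more.

    The path terminates early (returning the number of lambdas actually
    solved) once the training deviance ratio exceeds ``devmax`` or its
    fractional gain per step falls below ``fdev`` — the convention of
    reference regularization-path solvers. Pass fdev <= 0 to disable.
    """
    nlam = lambdas.shape[0]
    n, p = X.shape
    W = np.zeros((nlam, p))
    w = np.zeros(p)
    r = y.copy()
    G = np.empty((0, 0))
    g = np.empty(0)
    var_y = np.mean(y**2)  # y is centered
    if use_gram:
        G = np.ascontiguousarray(X.T @ X) / n
        g = X.T @ y / n  # gradient at w = 0
        c = g.copy()
    dev_prev = 0.0
    n_used = nlam
    for k in range(nlam):
        lam = lambdas[k]
        lam_l1 = lam * alpha
        denom = 1.0 + lam * (1.0 - alpha)
        for _ in range(max_sweeps):
            if use_gram:
                delta = _cd_sweep_gram(G, g, w, lam_l1, denom, False)
            else:
                delta = _cd_sweep(X, r, w, lam_l1, denom, False)
            if delta < thresh:
                break
            for _ in range(max_sweeps):
                if use_gram:
                    d2 = _cd_sweep_gram(G, g, w, lam_l1, denom, True)
                else:
                    d2 = _cd_sweep(X, r, w, lam_l1, denom, True)
                if d2 < thresh:
                    break
        W[k] = w
        if fdev > 0.0:
            if use_gram:
                mse = var_y - np.dot(w, c) - np.dot(w, g)
            else:
                mse = np.mean(r**2)
            dev = 1.0 - mse / var_y
            # the fractional-gain rule only applies once the fit is real:
            # at the top of the grid dev can sit at exactly 0 for several
            # lambdas (the fold's own lambda_max may lie below the grid)
            if dev > devmax or (dev_prev > 0.0 and dev - dev_prev < fdev * dev):
                n_used = k + 1
                break
            dev_prev = dev
    return W, n_used


# ---------------------------------------------------------------------------
# public fitting API


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = np.sqrt(((X - mu) ** 2).mean(axis=0))
    keep = sd > 1e-12
    return mu, sd, keep


def lambda_grid(Xs: np.ndarray, yc: np.ndarray, alpha: float, nlambda: int) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max (smallest lambda zeroing
    every coefficient for alpha > 0) down to lambda_max * lambda_min_ratio."""
    n, p = Xs.shape
    grid_alpha = max(alpha, RIDGE_GRID_ALPHA)
    # the tiny inflation keeps every coefficient exactly zero at lambda_max
    # despite rounding differences between this dot product and the solver's
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * grid_alpha) * (1 + 1e-10)
    if lam_max <= 0:
        raise DegenerateDesignError("response is orthogonal to every predictor")
    ratio = 0.01 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * ratio, nlambda)


def fit_path(
    M,
    age,
    penalty: PenaltySpec,
    nlambda: int = NLAMBDA_DEFAULT,
    lambdas: np.ndarray | None = None,
    tol: float = TOL_DEFAULT,
    feature_names: Sequence[str] | None = None,
    early_stop: bool | None = None,
) -> RegularizationPath:
    """Fit the regularization path on an n x p M-value matrix.

    When the grid is computed internally, the path may terminate before
    nlambda values once the training fit saturates (deviance ratio above
    0.999 or fractional gain below 1e-5 per step) — the returned path is
    then shorter than nlambda. An explicitly supplied ``lambdas`` grid is
    always solved in full. Zero-variance probes are dropped (with a
    warning) and get zero weight. Raises :class:`DegenerateDesignError`
    for a constant age vector.
    """
    if early_stop is None:
        early_stop = lambdas is None
    X = np.asarray(M, dtype=float)
    y = np.asarray(age, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"M {X.shape} and age {y.shape} are incompatible")
    n, p = X.shape
    if n < 2:
        raise DegenerateDesignError("need at least 2 samples")
    if p < 1:
        raise DegenerateDesignError("need at least 1 probe")
    if np.ptp(y) == 0:
        raise DegenerateDesignError("age vector is constant")
    if np.isnan(X).any():
        raise ValueError("M contains missing values; impute/filter first")
    if feature_names is None:
        feature_names = (list(M.columns) if isinstance(M, pd.DataFrame)
                         else [f"x{j}" for j in range(p)])
    feature_names = list(feature_names)

    mu, sd, keep = _standardize(X)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance probes")
    if not keep.any():
        raise DegenerateDesignError("all probes have zero variance")
    Xs = np.asfortranarray((X[:, keep] - mu[keep]) / sd[keep])
    ybar = y.mean()
    yc = y - ybar

    if lambdas is None:
        lambdas = lambda_grid(Xs, yc, penalty.alpha, nlambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")

    # convergence threshold on coefficient moves, scaled by the response SD
    # (the convention of reference coordinate-descent solvers): a sweep whose
    # largest update satisfies delta^2 < tol * var(y) has converged
    thresh = np.sqrt(tol * np.mean(yc**2))
    use_gram = n > Xs.shape[1] // 2  # Gram updates win once n ~ p/2
    fdev = PATH_FDEV if early_stop else 0.0
    Wk, n_used = _cd_path_kernel(Xs, yc, lambdas, penalty.alpha, thresh,
                                 MAX_SWEEPS, use_gram, fdev, PATH_DEVMAX)
    if n_used < len(lambdas):
        lambdas = lambdas[:n_used]
        Wk = Wk[:n_used]

    coef_std = np.zeros((len(lambdas), p))
    coef_std[:, keep] = Wk
    coef = np.zeros_like(coef_std)
    coef[:, keep] = Wk / sd[keep]
    intercept = ybar - coef @ mu
    return RegularizationPath(
        lambdas=lambdas, coef_std=coef_std, coef=coef, intercept=intercept,
        feature_names=feature_names, x_mean=mu, x_sd=sd, alpha=penalty.alpha,
    )


def elastic_net_objective(Xs, yc, w, lam, alpha) -> float:
    """Objective value in standardized space (used by tests and KKT checks)."""
    r = yc - Xs @ w
    n = Xs.shape[0]
    return float(
        0.5 * np.dot(r, r) / n
        + lam * (alpha * np.abs(w).sum() + 0.5 * (1 - alpha) * np.dot(w, w))
    )


def kkt_violation(Xs, yc, w, lam, alpha) -> float:
    """Maximal violation of the subgradient optimality conditions.

    At the optimum, for each coordinate j (g = x_j'r/n):
      w_j != 0:  g - lam*(1-alpha)*w_j == lam*alpha*sign(w_j)
      w_j == 0:  |g| <= lam*alpha
    Returns the largest absolute excess over these conditions.
    """
    n = Xs.shape[0]
    g = Xs.T @ (yc - Xs @ w) / n
    viol = np.where(
        w != 0.0,
        np.abs(g - lam * (1 - alpha) * w - lam * alpha * np.sign(w)),
        np.maximum(np.abs(g) - lam * alpha, 0.0),
    )
    return float(viol.max(initial=0.0))


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, n_folds)]


def cross_validate_lambda(
    M,
    age,
    penalty: PenaltySpec,
    nlambda: int = NLAMBDA_DEFAULT,
    seed: int = 0,
    tol: float = TOL_DEFAULT,
):
    """Choose lambda by held-out mean squared error.

    10 random folds when n >= 10, else leave-one-out; the lambda grid is
    computed once on the full data and shared by every fold. Returns
    ``(lambda_selected, path)`` where the path carries the CV curve; ties in
    the curve resolve to the largest (most penalized) lambda.
    """
    X = np.asarray(M, dtype=float)
    y = np.asarray(age, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DegenerateDesignError(f"cross-validation needs n >= 3, got {n}")
    path = fit_path(M, age, penalty, nlambda=nlambda, tol=tol)
    lambdas = path.lambdas

    n_folds = 10 if n >= 10 else n
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, n_folds, rng)

    sq_err = np.zeros((len(lambdas), n))
    fold_mse = np.zeros((len(lambdas), n_folds))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        # fold paths may terminate early like the master path; past the
        # truncation point the last computed model is carried forward
        sub = fit_path(X[train_idx], y[train_idx], penalty, lambdas=lambdas,
                       tol=tol, early_stop=True)
        nk = len(sub.lambdas)
        intercepts = np.concatenate([sub.intercept,
                                     np.repeat(sub.intercept[-1], len(lambdas) - nk)])
        coefs = np.vstack([sub.coef,
                           np.repeat(sub.coef[-1:], len(lambdas) - nk, axis=0)])
        pred = intercepts[:, None] + coefs @ X[test_idx].T
        err = (pred - y[test_idx][None, :]) ** 2
        sq_err[:, test_idx] = err
        fold_mse[:, f] = err.mean(axis=1)
    cv_mse = sq_err.mean(axis=1)
    cv_se = fold_mse.std(axis=1, ddof=1) / np.sqrt(n_folds)
    path.cv_mse = cv_mse
    path.cv_se = cv_se
    path.cv_n_folds = n_folds
    k = int(np.argmin(cv_mse))  # argmin returns the first (largest-lambda) tie
    return float(lambdas[k]), path


def fit_clock(
    m_values: pd.DataFrame,
    age,
    penalty: PenaltySpec,
    seed: int = 0,
    nlambda: int = NLAMBDA_DEFAULT,
    *,
    tissue: str = "",
    sex_config: str = "joint",
    training_gse_ids: Sequence[str] = (),
    subsample_size: int | None = None,
    tol: float = TOL_DEFAULT,
) -> ClockModel:
    """Train a clock on a preprocessed probes x samples M-value frame.

    Cross-validates lambda, refits nothing (the CV path on the full data
    already contains the solution at the selected lambda), and packages the
    sparse model with its provenance.
    """
    X = m_values.to_numpy(dtype=float).T  # samples x probes
    y = np.asarray(age, dtype=float)
    lam, path = cross_validate_lambda(X, y, penalty, nlambda=nlambda, seed=seed, tol=tol)
    k = int(np.where(path.lambdas == lam)[0][0])
    names = list(m_values.index)
    coef = path.coef[k]
    coef_std = path.coef_std[k]
    nz = coef != 0.0
    return ClockModel(
        intercept=float(path.intercept[k]),
        coefficients={names[j]: float(coef[j]) for j in np.where(nz)[0]},
        penalty=penalty,
        lambda_selected=lam,
        tissue=tissue,
        sex_config=sex_config,
        n_train=int(y.shape[0]),
        training_gse_ids=tuple(training_gse_ids),
        subsample_size=int(subsample_size if subsample_size is not None else y.shape[0]),
        seed=int(seed),
        coefficients_std={names[j]: float(coef_std[j]) for j in np.where(nz)[0]},
    )


def predict_methylage(model: ClockModel, m_values: pd.DataFrame) -> pd.Series:
    """Apply a clock to a probes x samples M-value frame.

    Probes in the frame but not in the model are ignored; model CpGs missing
    from the frame raise :class:`MissingProbeError` listing the ids.
    """
    cpgs = list(model.coefficients)
    missing = sorted(set(cpgs) - set(m_values.index))
    if missing:
        raise MissingProbeError(f"model CpGs absent from matrix: {missing}")
    if cpgs:
        w = np.array([model.coefficients[c] for c in cpgs])
        vals = m_values.loc[cpgs].to_numpy(dtype=float)
        pred = model.intercept + w @ vals
    else:
        pred = np.full(m_values.shape[1], model.intercept)
    return pd.Series(pred, index=m_values.columns, name="methylage")
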