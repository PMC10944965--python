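"""Random-intercept mixed models comparing clock performance.

Each comparison fits, on a long-format score table,

    Score ~ log(Sample size) [+ contrast dummy] + (1 | GSE),

by restricted maximum likelihood, with the response and every covariate
(dummies included) z-scored first so the fixed-effect slope of the contrast
is interpretable as a partial correlation. The random intercept on the
dataset of origin (GSE) absorbs cohort-level shifts; `log` is the natural
logarithm (the partial correlation is base-invariant after standardization).

The REML fit profiles the likelihood over the variance ratio
theta = tau^2 / sigma^2 (a one-dimensional optimization; the random-intercept
structure makes V = I + theta*ZZ' block diagonal and analytically
invertible), with GLS fixed effects given theta. Wald t-tests use the
conservative df = n_obs - n_fixed - n_groups, and p-values within a reported
family are adjusted by the Benjamini-Yekutieli step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError

FORMULA_IDS = ("size", "penalty", "sex_specific", "tissue_pair", "tissue_specific")


@dataclass(frozen=True)
class MixedModelSpec:
    """One contrast to fit: which dummy, on which response, grouped by GSE."""

    formula_id: str
    response: str = "adjusted_r2"
    contrast: tuple[str, str] | None = None  # pair of levels for penalty/tissue
    group_var: str = "gse_id"

    def __post_init__(self):
        if self.formula_id not in FORMULA_IDS:
            raise ValueError(f"unknown formula_id {self.formula_id!r}")
        if self.formula_id in ("penalty", "tissue_pair") and self.contrast is None:
            raise ValueError(f"{self.formula_id} requires a contrast pair")


@dataclass
class ComparisonResult:
    """One fixed-effect contrast: standardized partial slope with its test."""

    formula_id: str
    response: str
    contrast: str
    tissue: str
    partial_corr: float
    se: float
    t_statistic: float
    df: int
    p_value: float
    p_by: float | None
    group_var: float  # tau^2
    resid_var: float  # sigma^2
    n_obs: int
    n_groups: int


@dataclass
class LMMFit:
    """REML fit of y = X beta + Z u + e with a single random intercept."""

    beta: np.ndarray
    se: np.ndarray
    tau2: float
    sigma2: float
    theta: float  # tau2 / sigma2
    n_obs: int
    n_groups: int
    n_fixed: int
    reml_criterion: float

    @property
    def df(self) -> int:
        return self.n_obs - self.n_fixed - self.n_groups


def standardize(v, name: str = "variable") -> np.ndarray:
    """z-score with the n-1 denominator; raises on zero variance."""
    arr = np.asarray(v, dtype=float)
    if arr.size < 2:
        raise DegenerateDesignError(f"{name}: need length >= 2 to standardize")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDesignError(f"{name}: zero variance, cannot standardize")
    return (arr - arr.mean()) / sd


def _group_blocks(groups) -> list[np.ndarray]:
    codes, _ = pd.factorize(np.asarray(groups), sort=True)
    return [np.where(codes == g)[0] for g in range(codes.max() + 1)]


def _reml_pieces(theta: float, y, X, blocks):
    """Sufficient statistics of the profiled REML criterion at theta.

    Exploits V = I + theta * Z Z' being block diagonal with blocks
    I + theta * J, whose inverse is I - theta/(1 + theta*n_g) * J.
    """
    XtVX = X.T @ X
    XtVy = X.T @ y
    ytVy = float(y @ y)
    logdetV = 0.0
    for idx in blocks:
        ng = idx.size
        c = theta / (1.0 + theta * ng)
        sx = X[idx].sum(axis=0)
        sy = float(y[idx].sum())
        XtVX -= c * np.outer(sx, sx)
        XtVy -= c * sx * sy
        ytVy -= c * sy * sy
        logdetV += np.log1p(theta * ng)
    return XtVX, XtVy, ytVy, logdetV


def _reml_criterion(theta: float, y, X, blocks) -> float:
    n, p = X.shape
    XtVX, XtVy, ytVy, logdetV = _reml_pieces(theta, y, X, blocks)
    sign, logdetA = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    if rss <= 0:
        return np.inf
    return logdetV + logdetA + (n - p) * np.log(rss)


def fit_random_intercept_lmm(y, X, groups) -> LMMFit:
    """REML fit of a linear mixed model with one random intercept.

    Parameters
    ----------
    y : response vector
    X : fixed-effects design matrix (include the intercept column yourself)
    groups : per-observation grouping labels (the GSE of each score)
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X lengths differ")
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError("fixed-effects design is singular")
    blocks = _group_blocks(groups)
    if len(blocks) < 2:
        raise DegenerateDesignError("need >= 2 grouping levels for a random intercept")
    if n - p - len(blocks) < 1:
        raise DegenerateDesignError("not enough observations for the t-test df")

    obj = lambda log10_theta: _reml_criterion(10.0 ** log10_theta, y, X, blocks)
    res = optimize.minimize_scalar(obj, bounds=(-8.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(10.0 ** res.x)
    crit = float(res.fun)
    crit0 = _reml_criterion(0.0, y, X, blocks)
    if crit0 <= crit:  # boundary solution: no group variance
        theta, crit = 0.0, float(crit0)

    XtVX, XtVy, ytVy, _ = _reml_pieces(theta, y, X, blocks)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)
    sigma2 = rss / (n - p)  # REML variance estimate
    cov = sigma2 * np.linalg.inv(XtVX)
    return LMMFit(
        beta=beta, se=np.sqrt(np.diag(cov)), tau2=theta * sigma2,
        sigma2=sigma2, theta=theta, n_obs=n, n_groups=len(blocks),
        n_fixed=p, reml_criterion=crit,
    )


def wald_t(estimate: float, se: float, df: int) -> tuple[float, float]:
    """One-sample t-test of a coefficient against zero."""
    if se <= 0:
        raise ValueError("se must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = estimate / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))


def by_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under arbitrary
    dependence): BH multiplied by c(m) = sum_{i<=m} 1/i."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_by")
    return adjusted


def _dummy_and_rows(frame: pd.DataFrame, spec: MixedModelSpec):
    """Select the relevant rows and build the 0/1 contrast dummy."""
    if spec.formula_id == "size":
        return frame, None, "log_sample_size"
    if spec.formula_id == "penalty":
        a, b = spec.contrast
        sub = frame[frame["penalty"].isin([a, b])]
        levels = set(sub["penalty"])
        if levels != {a, b}:
            raise DegenerateDesignError(f"penalty levels present: {sorted(levels)}, need {a}, {b}")
        return sub, (sub["penalty"] == b).astype(float), f"{b}_vs_{a}"
    if spec.formula_id == "sex_specific":
        sub = frame[frame["validation_sex"].isin(["male", "female"])]
        dummy = (sub["sex_config"] != "joint").astype(float)
        if dummy.nunique() < 2:
            raise DegenerateDesignError("need both sex-specific and joint clocks")
        return sub, dummy, "sex_specific_vs_joint"
    if spec.formula_id == "tissue_pair":
        a, b = spec.contrast
        sub = frame[frame["tissue"].isin([a, b])]
        levels = set(sub["tissue"])
        if levels != {a, b}:
            raise DegenerateDesignError(f"tissue levels present: {sorted(levels)}, need {a}, {b}")
        return sub, (sub["tissue"] == b).astype(float), f"{b}_vs_{a}"
    # tissue_specific
    dummy = frame["tissue_specific"].astype(float)
    if dummy.nunique() < 2:
        raise DegenerateDesignError("need both blood-trained and tissue-trained scores")
    return frame, dummy, "tissue_vs_blood"


def compare(scores, spec: MixedModelSpec, tissue_label: str = "all") -> ComparisonResult:
    """Fit one mixed-model contrast on a score table.

    ``scores`` is a DataFrame in the long score format (or a list of
    ScoreRecord). The covariate of interest is the contrast dummy (or
    log sample size itself for the size model); its standardized slope is
    returned as a partial correlation with a Wald t-test. ``p_by`` is left
    unset: adjustment happens per reporting family via :func:`adjust_family`.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame([r.as_dict() for r in scores])
    frame, dummy, contrast_name = _dummy_and_rows(scores, spec)
    if frame.shape[0] < 4:
        raise DegenerateDesignError("too few score rows for a mixed model")

    y = standardize(frame[spec.response], spec.response)
    logn = standardize(np.log(frame["subsample_size"].astype(float)), "log_sample_size")
    cols = [np.ones(len(frame)), logn]
    interest = 1  # index of log size
    if dummy is not None:
        cols.append(standardize(dummy, contrast_name))
        interest = 2
    X = np.column_stack(cols)
    fit = fit_random_intercept_lmm(y, X, frame[spec.group_var])
    est, se = float(fit.beta[interest]), float(fit.se[interest])
    t, p = wald_t(est, se, fit.df)
    return ComparisonResult(
        formula_id=spec.formula_id, response=spec.response,
        contrast=contrast_name, tissue=tissue_label,
        partial_corr=est, se=se, t_statistic=t, df=fit.df, p_value=p,
        p_by=None, group_var=fit.tau2, resid_var=fit.sigma2,
        n_obs=fit.n_obs, n_groups=fit.n_groups,
    )


def adjust_family(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """BY-adjust the p-values of one reporting family together."""
    results = list(results)
    if not results:
        return []
    adjusted = by_adjust([r.p_value for r in results])
    return [replace(r, p_by=float(q)) for r, q in zip(results, adjusted)]


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in results])
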