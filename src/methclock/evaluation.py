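"""Clock performance scores from the methylage ~ age calibration regression.

A trained clock is assessed by regressing its predicted methylage on
chronological age,

    methylage = theta1 + theta2 * age + residuals,

and summarizing the fit by two scores: the RMSE of the residuals about the
fitted line (NOT about the identity line — a constant bias in methylage is
absorbed by theta1) and the adjusted R-squared with the parameter count K
fixed at 2 (intercept and slope):

    RMSE      = sqrt( (1/n) * sum (y_i - yhat_i)^2 )
    adj. R^2  = 1 - [ (1/(n-K)) sum (y_i - yhat_i)^2 ]
                    / [ (1/(n-1)) sum (y_i - ybar)^2 ].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError

K_PREDICTORS = 2  # parameters of the calibration line: intercept + slope


@dataclass
class CalibrationFit:
    """OLS fit of methylage on chronological age."""

    theta1: float  # intercept, years
    theta2: float  # slope, dimensionless
    n: int
    y: np.ndarray  # observed methylage
    fitted: np.ndarray  # theta1 + theta2 * age
    residuals: np.ndarray


@dataclass
class ScoreRecord:
    """One (clock, evaluation-split) outcome with its experimental labels.

    ``split`` is training/test/validation; ``gse_id`` names the held-out
    validation dataset (or "pooled"); ``tissue_specific`` is False for a
    blood-trained clock transferred to another tissue. When produced by
    :mod:`methclock.synthetic` score-table simulation, ``adjusted_r2``
    carries a synthetic score on an arbitrary scale.
    """

    adjusted_r2: float
    rmse: float
    split: str
    n: int
    gse_id: str
    tissue: str
    penalty: str
    sex_config: str
    validation_sex: str
    subsample_size: int
    tissue_specific: bool

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tissue_specific"] = int(self.tissue_specific)
        return d


def fit_calibration(methylage, age) -> CalibrationFit:
    """Ordinary least squares of methylage on age."""
    y = np.asarray(methylage, dtype=float)
    x = np.asarray(age, dtype=float)
    if y.shape != x.shape:
        raise ValueError("methylage and age lengths differ")
    n = y.shape[0]
    if n < 3:
        raise DegenerateDesignError(f"calibration needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("age vector is constant")
    xc = x - x.mean()
    theta2 = float(np.dot(xc, y) / np.dot(xc, xc))
    theta1 = float(y.mean() - theta2 * x.mean())
    fitted = theta1 + theta2 * x
    return CalibrationFit(theta1=theta1, theta2=theta2, n=n, y=y,
                          fitted=fitted, residuals=y - fitted)


def rmse(fit: CalibrationFit) -> float:
    """Root mean squared residual about the calibration line, in years."""
    return float(np.sqrt(np.mean(fit.residuals**2)))


def adjusted_r2(fit: CalibrationFit) -> float:
    """Adjusted R-squared of the calibration regression with K = 2."""
    n = fit.n
    if n <= K_PREDICTORS:
        raise DegenerateDesignError(f"adjusted R2 needs n > {K_PREDICTORS}")
    ss_tot = float(np.sum((fit.y - fit.y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDesignError("methylage has zero variance")
    ss_res = float(np.sum(fit.residuals**2))
    return 1.0 - (ss_res / (n - K_PREDICTORS)) / (ss_tot / (n - 1))


def score_clock(
    model,
    m_values: pd.DataFrame,
    age,
    *,
    split: str,
    gse_id: str = "pooled",
    tissue: str = "",
    validation_sex: str = "joint",
    tissue_specific: bool = True,
) -> ScoreRecord | None:
    """Predict, calibrate and score a clock on one evaluation split.

    Returns ``None`` (a skip signal, not an error) when fewer than three
    evaluable samples are available, mirroring the >= 3-samples guard used
    throughout the benchmark.
    """
    from .clock import predict_methylage

    y = np.asarray(age, dtype=float)
    if y.shape[0] < 3 or np.ptp(y) == 0:
        return None
    pred = predict_methylage(model, m_values).to_numpy()
    if np.ptp(pred) == 0:
        # an intercept-only clock carries no calibration information; score
        # it as uninformative rather than failing
        fit_r2, fit_rmse = 0.0, float(np.sqrt(np.mean((pred - pred.mean()) ** 2)))
    else:
        fit = fit_calibration(pred, y)
        fit_r2, fit_rmse = adjusted_r2(fit), rmse(fit)
    return ScoreRecord(
        adjusted_r2=fit_r2,
        rmse=fit_rmse,
        split=split,
        n=int(y.shape[0]),
        gse_id=gse_id,
        tissue=tissue or model.tissue,
        penalty=model.penalty.name,
        sex_config=model.sex_config,
        validation_sex=validation_sex,
        subsample_size=model.subsample_size,
        tissue_specific=tissue_specific,
    )
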