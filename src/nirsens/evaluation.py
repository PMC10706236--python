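"""Figures of merit and model-adequacy tests for calibration models.

RMSE, coefficient of determination (1 - SSE/SST, not a squared correlation),
percentual relative standard deviation (RSD% = 100 * RMSEP / mean of the
observed prediction-set values — the denominator convention is declared in
every report), the elliptical joint confidence region (EJCR) for the
(intercept, slope) of the observed-vs-predicted regression, and the
Durbin-Watson first-order autocorrelation test on prediction residuals.

EJCR orientation: predicted is regressed on observed (an ``orientation``
flag flips this).  The joint 100(1-alpha)% region is the classical F-based
ellipse; the model is accurate when the region contains the ideal point
(intercept 0, slope 1).

DW probability: normal approximation to the null distribution,
DW ~ N(2, 4/n); adequate at the n of tens typical here, checked by
simulation in the test suite.  Residuals are ordered by observed value
before computing DW so the statistic responds to curvature (unmodeled
nonlinearity), which is what the test is used to detect.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .regression import FittedModel
from .selection import SplitResult

__all__ = [
    "rmse",
    "r_squared",
    "rsd_percent",
    "ejcr_test",
    "durbin_watson",
    "MeritReport",
    "merit_report",
]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size == 0:
        raise ValueError("empty observed/predicted vectors")
    if o.size != p.size:
        raise ValueError(f"length mismatch: {o.size} observed vs {p.size} predicted")
    return o, p


def rmse(observed, predicted) -> float:
    """Root-mean-square error, in the units of y."""
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    o, p = _pair(observed, predicted)
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return float(1.0 - np.sum((o - p) ** 2) / sst)


def rsd_percent(observed, predicted) -> float:
    """100 * RMSE / mean(observed) — relative prediction error in percent."""
    o, p = _pair(observed, predicted)
    m = float(o.mean())
    if m == 0:
        raise ValueError("mean of observed values is zero; RSD undefined")
    return float(100.0 * rmse(o, p) / m)


def ejcr_test(
    observed,
    predicted,
    alpha: float = 0.05,
    orientation: str = "predicted_on_observed",
) -> tuple[bool, dict]:
    """Elliptical joint confidence region test for (intercept, slope).

    Returns ``(contains_ideal, info)`` where ``info`` holds the fitted
    intercept/slope, the F statistic of the ideal point (0, 1), the critical
    value at ``alpha``, and a ``degenerate`` flag.  A zero-residual-variance
    regression is reported as containing the ideal point with the degenerate
    flag set.
    """
    o, p = _pair(observed, predicted)
    n = o.size
    if n < 3:
        raise ValueError("EJCR needs at least 3 points")
    if orientation == "predicted_on_observed":
        xr, yr = o, p
    elif orientation == "observed_on_predicted":
        xr, yr = p, o
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    Z = np.column_stack([np.ones(n), xr])
    beta, *_ = np.linalg.lstsq(Z, yr, rcond=None)
    resid = yr - Z @ beta
    rss = float(resid @ resid)
    info = {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "alpha": alpha,
        "orientation": orientation,
        "degenerate": False,
    }
    # degeneracy threshold relative to the response scale
    if rss <= 1e-24 * max(float(yr @ yr), 1e-300):
        info["degenerate"] = True
        info["f_statistic"] = 0.0
        info["f_critical"] = float(stats.f.ppf(1 - alpha, 2, n - 2))
        return True, info
    s2 = rss / (n - 2)
    delta = beta - np.array([0.0, 1.0])
    f_stat = float(delta @ (Z.T @ Z) @ delta / (2.0 * s2))
    f_crit = float(stats.f.ppf(1 - alpha, 2, n - 2))
    info["f_statistic"] = f_stat
    info["f_critical"] = f_crit
    return f_stat <= f_crit, info


def durbin_watson(residuals) -> tuple[float, float]:
    """Durbin-Watson statistic and its normal-approximation probability.

    ``DW = sum (e_t - e_{t-1})^2 / sum e_t^2``; under the null of no
    first-order autocorrelation DW is approximately N(2, 4/n), giving a
    two-sided probability.  All-zero residuals are an error.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 3:
        raise ValueError("Durbin-Watson needs at least 3 residuals")
    if np.all(e == 0):
        raise ValueError("all residuals are zero; DW undefined")
    d = float(_sm_dw(e))
    z = abs(d - 2.0) / np.sqrt(4.0 / e.size)
    p = float(2.0 * (1.0 - stats.norm.cdf(z)))
    return d, p


@dataclasses.dataclass
class MeritReport:
    """One attribute's row of figures of merit (calibration + prediction)."""

    attribute: str
    rmsec: float
    rmsep: float
    r2_cal: float
    r2_pred: float
    rsd_pred_pct: float
    ejcr_contains_ideal: bool
    ejcr_alpha: float
    dw_statistic: float
    dw_probability: float
    model_params: dict
    rsd_convention: str = "100 * RMSEP / mean(observed prediction-set values)"

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsep < 0 or self.rsd_pred_pct < 0:
            raise ValueError("rmse/rsd must be >= 0")
        if self.r2_cal > 1 + 1e-12 or self.r2_pred > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")
        if not 0.0 <= self.dw_statistic <= 4.0:
            raise ValueError("DW statistic must lie in [0, 4]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MeritReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "MeritReport":
        return cls.from_dict(json.loads(text))


def merit_report(
    model: FittedModel,
    X,
    y: np.ndarray,
    split: SplitResult,
    attribute: str = "",
    alpha: float = 0.05,
) -> MeritReport:
    """Assemble all figures of merit for one fitted model and split.

    ``X`` is whatever the model predicts from (a raw :class:`SpectraSet` if
    the model carries a preprocessor, else a matrix); ``y`` covers all rows.
    DW is computed on prediction residuals ordered by observed value.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(X)
    cal, pred = split.calibration_idx, split.prediction_idx
    o_pred, p_pred = y[pred], yhat[pred]
    contains, info = ejcr_test(o_pred, p_pred, alpha=alpha)
    order = np.argsort(o_pred, kind="stable")
    dw_stat, dw_p = durbin_watson((o_pred - p_pred)[order])
    if isinstance(model.spec, dict):
        params = dict(model.spec)
    else:
        params = {k: v for k, v in model.spec.to_dict().items() if v is not None}
    return MeritReport(
        attribute=attribute,
        rmsec=rmse(y[cal], yhat[cal]),
        rmsep=rmse(o_pred, p_pred),
        r2_cal=r_squared(y[cal], yhat[cal]),
        r2_pred=r_squared(o_pred, p_pred),
        rsd_pred_pct=rsd_percent(o_pred, p_pred),
        ejcr_contains_ideal=bool(contains),
        ejcr_alpha=alpha,
        dw_statistic=dw_stat,
        dw_probability=dw_p,
        model_params=params,
    )
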