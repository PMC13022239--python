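"""h-step-ahead forecasting with Gaussian 95% prediction intervals.

Forecasts come from the same state-space recursion used for the likelihood:
the filtered state at the forecast origin is propagated forward without
updates, the point forecast being the regression mean plus the predicted
error-process mean and the forecast variance sigma^2 * P[0,0].  Intervals
ignore parameter-estimation uncertainty, as is standard for ARIMA-type
forecasting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._filter import predict_ahead
from .armax import FittedModel, _filter_once, _mean_vector

__all__ = ["ForecastResult", "forecast_h", "forecast_series", "rolling_one_step",
           "standardized_errors", "rmse"]


@dataclass
class ForecastResult:
    """Point forecasts with prediction-interval bounds (consumption units)."""

    mean: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    index: object = None
    actual: np.ndarray | None = None
    std_errors: np.ndarray | None = None
    rmse: float | None = None

    def __post_init__(self):
        if np.any(self.lower > self.mean) or np.any(self.mean > self.upper):
            raise ValueError("interval bounds must bracket the point forecast")

    def with_actual(self, actual) -> "ForecastResult":
        actual = np.asarray(actual, dtype=float)
        self.actual = actual
        self.std_errors = standardized_errors(self, actual)
        self.rmse = rmse(self.mean, actual)
        return self

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"forecast": self.mean, "se": self.se,
                           "lo": self.lower, "hi": self.upper})
        if self.actual is not None:
            df["actual"] = self.actual
            df["std_error"] = self.std_errors
        if self.index is not None:
            df.index = self.index
        return df


def _interval(mean, se, level):
    z = stats.norm.ppf(0.5 + level / 2)
    return mean - z * se, mean + z * se


def forecast_h(fitted: FittedModel, h: int, X_future: pd.DataFrame | None = None,
               level: float = 0.95) -> ForecastResult:
    """Forecast h steps ahead from the end of the training sample."""
    if h <= 0:
        raise ValueError("h must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    spec, params = fitted.spec, fitted.params
    if spec.regressors:
        if X_future is None:
            raise ValueError(f"future values required for regressors {spec.regressors}")
        missing = [r for r in spec.regressors if r not in X_future.columns]
        if missing:
            raise ValueError(f"future covariates missing: {missing}")
        if len(X_future) < h:
            raise ValueError("X_future must have at least h rows")
    a, P = fitted.filter_state
    from .armax import _phic_rvec  # local import to avoid cycle at module load

    phic, rvec = _phic_rvec(spec, params)
    err_mean, err_var = predict_ahead(a, P, phic, rvec, h)
    reg_mean = _mean_vector(spec, params, X_future.iloc[:h] if X_future is not None else None, h)
    mean = reg_mean + err_mean
    se = np.sqrt(err_var * params.sigma2)
    lo, hi = _interval(mean, se, level)
    idx = X_future.index[:h] if X_future is not None else None
    return ForecastResult(mean=mean, se=se, lower=lo, upper=hi, level=level, index=idx)


def forecast_series(fitted: FittedModel, y_history, X_history: pd.DataFrame | None,
                    X_future: pd.DataFrame | None, h: int, level: float = 0.95) -> ForecastResult:
    """Filter a (possibly new) series' history with the fitted parameters,
    then forecast ``h`` steps beyond its end (fixed-origin multi-step)."""
    y_history = np.asarray(y_history, dtype=float)
    if y_history.size:
        *_, a, P, mean, phic, rvec = _filter_once(fitted.spec, fitted.params, y_history, X_history)
    else:
        from .armax import _phic_rvec, _stationary_cov

        phic, rvec = _phic_rvec(fitted.spec, fitted.params)
        a = np.zeros(phic.shape[0])
        P = _stationary_cov(phic, rvec)
    err_mean, err_var = predict_ahead(a, P, phic, rvec, h)
    reg_mean = _mean_vector(fitted.spec, fitted.params,
                            X_future.iloc[:h] if X_future is not None else None, h)
    mean = reg_mean + err_mean
    se = np.sqrt(err_var * fitted.params.sigma2)
    lo, hi = _interval(mean, se, level)
    idx = X_future.index[:h] if X_future is not None else None
    return ForecastResult(mean=mean, se=se, lower=lo, upper=hi, level=level, index=idx)


def rolling_one_step(fitted: FittedModel, y_new, X_new: pd.DataFrame | None = None,
                     level: float = 0.95) -> ForecastResult:
    """One-step-ahead rolling forecasts over a held-out series.

    Runs the filter with the trained parameters from the stationary initial
    state; each step's prediction uses only earlier observations of the new
    series.  On the training sample itself, the resulting forecast errors are
    the model's innovations.
    """
    y_new = np.asarray(y_new, dtype=float)
    sumlogF, ssq, nobs, v, F, *_ , mean, phic, rvec = _filter_once(
        fitted.spec, fitted.params, y_new, X_new
    )
    pred = np.where(np.isfinite(v), y_new - v, np.nan)
    se = np.sqrt(F * fitted.params.sigma2)
    lo, hi = _interval(pred, se, level)
    idx = X_new.index if X_new is not None else None
    res = ForecastResult(mean=pred, se=se,
                         lower=np.where(np.isfinite(pred), lo, np.nan),
                         upper=np.where(np.isfinite(pred), hi, np.nan),
                         level=level, index=idx)
    return res.with_actual(y_new)


def standardized_errors(result: ForecastResult, actual) -> np.ndarray:
    """(actual - point forecast) / forecast SE, per step."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape != result.mean.shape:
        raise ValueError("actual must align with the forecast horizon")
    if np.any(result.se[np.isfinite(result.se)] <= 0):
        raise ValueError("forecast SEs must be positive")
    return (actual - result.mean) / result.se


def rmse(predicted, actual) -> float:
    """Root mean squared error over non-missing pairs."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have equal length")
    ok = np.isfinite(p) & np.isfinite(a)
    if not ok.any():
        raise ValueError("no overlapping non-missing pairs")
    d = p[ok] - a[ok]
    return float(np.sqrt(np.mean(d * d)))
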