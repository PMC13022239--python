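"""Deterministic regressor matrix: harmonic seasonal terms, fattening-day
trend, and environmental covariates.

The daily cycle is represented by the first four harmonics of the 24-h period
(24, 12, 8 and 6 h), i.e. column pairs sin(2*pi*k*h/24), cos(2*pi*k*h/24) for
k = 1..4, named S1..S4 and C1..C4.  Phase zero is local midnight; the hour
index enters modulo 24, so cumulative and within-day hour indices give the
same columns for periods dividing 24 h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import HourlySeries

DEFAULT_COVARIATES = ("temperature", "ammonia")

#: short names used in coefficient tables for common covariates
COVARIATE_LABELS = {"temperature": "T", "ammonia": "NH3", "fattening_day": "N"}


def harmonic_design(hour_of_day, n_harmonics: int = 4, base_period: float = 24.0) -> pd.DataFrame:
    """Sine/cosine columns for the first ``n_harmonics`` of ``base_period``.

    Column order is S1..Sk then C1..Ck.
    """
    if base_period <= 0:
        raise ValueError("base_period must be > 0")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    h = np.asarray(hour_of_day, dtype=float)
    cols = {}
    for k in range(1, n_harmonics + 1):
        cols[f"S{k}"] = np.sin(2 * np.pi * k * h / base_period)
    for k in range(1, n_harmonics + 1):
        cols[f"C{k}"] = np.cos(2 * np.pi * k * h / base_period)
    return pd.DataFrame(cols)


def covariate_design(series: HourlySeries, choices) -> pd.DataFrame:
    """Selected covariate columns of a series, in the requested order.

    ``fattening_day`` (N = 1 + floor(hours since batch start / 24)) is always
    available; other names must exist on the series.
    """
    out = {}
    for name in choices:
        if name not in series.data.columns:
            raise KeyError(f"covariate '{name}' not present on series {series.key()}")
        out[name] = series.data[name].to_numpy(dtype=float)
    return pd.DataFrame(out, index=range(series.n_hours))


def design_matrix(
    series: HourlySeries,
    n_harmonics: int = 4,
    covariates=DEFAULT_COVARIATES,
    include_trend: bool = True,
) -> pd.DataFrame:
    """Full design: harmonics, then covariates, then the fattening-day trend.

    With the defaults this yields 11 columns
    (S1..S4, C1..C4, temperature, ammonia, fattening_day).
    """
    parts = [harmonic_design(series.hour_of_day(), n_harmonics=n_harmonics)]
    names = list(covariates)
    if include_trend and "fattening_day" not in names:
        names.append("fattening_day")
    if names:
        parts.append(covariate_design(series, names))
    X = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    if X.columns.duplicated().any():
        raise ValueError("duplicate design-matrix column names")
    # hours with a missing covariate cannot enter the likelihood: propagate
    # them into the series missing mask and zero-fill so X stays finite
    bad_rows = ~np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if bad_rows.any():
        mask = series.data["missing"].to_numpy(bool) | bad_rows
        series.data["missing"] = mask
        X = X.fillna(0.0)
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("non-finite (non-NaN) values in design matrix")
    return X
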