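"""Residual adequacy checks and descriptive analyses.

Residual checks: the Ljung-Box portmanteau test for leftover autocorrelation
(df = number of lags, matching common reporting practice for this analysis;
a fitted-parameter df adjustment is available), the Shapiro-Wilk normality
test (subsampled above its customary n = 5000 validity bound), and
residual-vs-fitted pairs for plotting.

Descriptive analyses: the per-hour consumption profile (optionally split into
hot months May-October vs cold months November-April), a one-way ANOVA of
consumption on hour of day, and the harmonic-curve overlay decomposing the
fitted daily cycle into its 24/12/8/6-h components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .armax import acf
from .design import harmonic_design
from .series import HourlySeries

__all__ = ["DiagnosticsReport", "ljung_box", "shapiro_wilk", "residual_report",
           "hourly_profile", "hour_anova", "harmonic_overlay", "HOT_MONTHS"]

HOT_MONTHS = frozenset({5, 6, 7, 8, 9, 10})  # May-October inclusive


def ljung_box(residuals, lags: int = 24, df_adjust: int = 0):
    """Ljung-Box Q = n(n+2) sum_{k<=lags} rho_k^2/(n-k) and its chi-square p.

    ``df_adjust`` subtracts fitted ARMA parameters from the degrees of
    freedom; the default df equals ``lags``.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    n = x.shape[0]
    if n <= lags:
        raise ValueError("residual length must exceed the number of lags")
    rho = acf(x, lags)[1:]
    k = np.arange(1, lags + 1)
    q = float(n * (n + 2) * np.sum(rho**2 / (n - k)))
    df = lags - df_adjust
    if df <= 0:
        raise ValueError("non-positive degrees of freedom after adjustment")
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def shapiro_wilk(residuals, max_n: int = 5000, seed: int = 0):
    """Shapiro-Wilk W and p; a seeded random subsample of ``max_n`` is used
    (and noted) when the series is longer than the statistic's validity bound."""
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 residuals")
    subsampled = x.shape[0] > max_n
    if subsampled:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
    w, p = stats.shapiro(x)
    return float(w), float(p), int(x.shape[0])


@dataclass
class DiagnosticsReport:
    """Residual adequacy summary for a fitted model."""

    ljung_box_q: float
    ljung_box_df: int
    ljung_box_p: float
    shapiro_w: float
    shapiro_p: float
    shapiro_n: int
    resid_mean: float
    resid_sd: float
    resid_skewness: float
    residual_vs_fitted: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "Residual diagnostics",
            f"  Ljung-Box Q({self.ljung_box_df}) = {self.ljung_box_q:.2f}, p = {self.ljung_box_p:.3f}",
            f"  Shapiro-Wilk W = {self.shapiro_w:.3f}, p = {self.shapiro_p:.3g} (n = {self.shapiro_n})",
            f"  residual mean = {self.resid_mean:.4f}, SD = {self.resid_sd:.4f}, "
            f"skewness = {self.resid_skewness:.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ljung_box_q": self.ljung_box_q,
            "ljung_box_df": self.ljung_box_df,
            "ljung_box_p": self.ljung_box_p,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
            "shapiro_n": self.shapiro_n,
            "resid_mean": self.resid_mean,
            "resid_sd": self.resid_sd,
            "resid_skewness": self.resid_skewness,
        }


def residual_report(fitted, y, lags: int = 24, df_adjust: int = 0, seed: int = 0) -> DiagnosticsReport:
    """Assemble the full residual diagnostics for a FittedModel."""
    resid = np.asarray(fitted.residuals, dtype=float)
    ok = np.isfinite(resid)
    q, df, p = ljung_box(resid[ok], lags=lags, df_adjust=df_adjust)
    w, wp, wn = shapiro_wilk(resid[ok], seed=seed)
    y = np.asarray(y, dtype=float)
    fitted_vals = np.where(ok, y - resid, np.nan)
    rvf = pd.DataFrame({"fitted": fitted_vals[ok], "residual": resid[ok]})
    return DiagnosticsReport(
        ljung_box_q=q, ljung_box_df=df, ljung_box_p=p,
        shapiro_w=w, shapiro_p=wp, shapiro_n=wn,
        resid_mean=float(resid[ok].mean()),
        resid_sd=float(resid[ok].std(ddof=1)),
        resid_skewness=float(stats.skew(resid[ok])),
        residual_vs_fitted=rvf,
    )


def hourly_profile(series: HourlySeries | pd.DataFrame, season: str = "all") -> pd.DataFrame:
    """Per-hour (0-23) mean, SD and count of consumption.

    ``season``: 'all', 'hot' (calendar months May-October) or 'cold'
    (November-April).
    """
    df = series.data if isinstance(series, HourlySeries) else series
    sub = df[~df["missing"].astype(bool)]
    if season == "hot":
        sub = sub[sub.index.month.isin(HOT_MONTHS)]
    elif season == "cold":
        sub = sub[~sub.index.month.isin(HOT_MONTHS)]
    elif season != "all":
        raise ValueError(f"unknown season '{season}'")
    if sub.empty:
        raise ValueError(f"no data after filtering to season '{season}'")
    g = sub.groupby(sub.index.hour)["consumption"]
    prof = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "count": g.size()})
    prof = prof.reindex(range(24))
    prof["count"] = prof["count"].fillna(0).astype(int)
    prof.index.name = "hour"
    prof["season"] = season
    return prof


def hour_anova(series: HourlySeries | pd.DataFrame):
    """One-way fixed-effects ANOVA of consumption on hour of day.

    Returns (F, df1, df2, p); df1 = 23 when all 24 hours are present.
    """
    df = series.data if isinstance(series, HourlySeries) else series
    sub = df[~df["missing"].astype(bool)]
    groups = [g.to_numpy(dtype=float) for _, g in sub.groupby(sub.index.hour)["consumption"]]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 hours with at least 2 observations each")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(g.size for g in groups) - len(groups)
    return float(f), df1, df2, float(p)


def harmonic_overlay(coefficients: dict, n_harmonics: int = 4) -> pd.DataFrame:
    """Evaluate each harmonic wave and their sum at hours 0-23.

    ``coefficients`` maps S1..Sk / C1..Ck to amplitudes (absent terms are 0).
    Returns a frame with one column per harmonic (H1..Hk) and their 'sum'.
    """
    hours = np.arange(24)
    H = harmonic_design(hours, n_harmonics=n_harmonics)
    out = pd.DataFrame(index=pd.Index(hours, name="hour"))
    total = np.zeros(24)
    for k in range(1, n_harmonics + 1):
        wave = (coefficients.get(f"S{k}", 0.0) * H[f"S{k}"].to_numpy()
                + coefficients.get(f"C{k}", 0.0) * H[f"C{k}"].to_numpy())
        out[f"H{k}"] = wave
        total += wave
    out["sum"] = total
    return out
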