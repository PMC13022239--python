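"""Synthetic barn-data generator.

Real barn records from commercial farms are rarely shareable, so the package
ships a generator that emulates the structure such analyses assume, in two
modes:

``model-truth``
    The exact subset-ARMAX equation with the published final-model
    coefficients (:data:`TABLE1_PHI`, :data:`TABLE1_THETA`, :data:`TABLE2_ETA`)
    and unit innovation SD.  The linear predictor may go negative; this mode
    exists to validate the estimator (parameter recovery), not to look like a
    farm.

``farm-realistic``
    Calibrated descriptive patterns: a saturating growth trend in daily
    intake (first-week mean 2.35 L/pig/day rising to an 8.05 L/pig/day
    plateau), a diurnal shape with a morning (8-12 h) bump and a dominant
    late-afternoon (16-17 h) peak, near-zero overnight drinking, lognormal
    AR(1) multiplicative noise, a linear ramp to zero over the final 3 days,
    and sensor corruption (negative spikes, extreme readings, consecutive-hour
    sums, missing records) logged in a fault ledger so cleaning can be scored
    exactly.

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .armax import ModelSpec, ParameterSet, check_stationary_invertible, simulate_armax
from .design import harmonic_design
from .series import HourlySeries

__all__ = [
    "TABLE1_PHI",
    "TABLE1_THETA",
    "TABLE2_ETA",
    "TABLE1_SE",
    "TABLE2_SE",
    "final_model_spec",
    "truth_parameters",
    "EnvironmentConfig",
    "BatchConfig",
    "CorruptionRates",
    "SimulatedBatch",
    "simulate_environment",
    "simulate_pig_counts",
    "mean_consumption_profile",
    "daily_total_curve",
    "diurnal_shape",
    "corrupt_readings",
    "simulate_batch",
    "simulate_farm",
]

# -- published final-model coefficients (ground truth for estimator validation)

TABLE1_PHI = {1: 1.1045, 2: -0.3326, 22: -0.2183, 23: 0.8993, 24: -0.4818}
TABLE1_THETA = {1: -0.6963, 2: 0.1583, 22: 0.2733, 23: -0.7566, 24: 0.2893}
TABLE1_SE = {
    "ar1": 0.1008, "ar2": 0.0454, "ar22": 0.0370, "ar23": 0.0666, "ar24": 0.0744,
    "ma1": 0.1033, "ma2": 0.0223, "ma22": 0.0411, "ma23": 0.0554, "ma24": 0.0625,
}
TABLE2_ETA = {
    "S1": -0.7513, "S2": -0.4167, "S3": 0.2275, "S4": 0.1351,
    "C1": -0.7394, "C2": -0.1976, "C3": 0.1960, "C4": 0.0482,
    "temperature": 0.0198, "ammonia": -0.0142, "fattening_day": -0.1196,
}
TABLE2_SE = {
    "S1": 0.0660, "S2": 0.0417, "S3": 0.0263, "S4": 0.0161,
    "C1": 0.0523, "C2": 0.0395, "C3": 0.0265, "C4": 0.0158,
    "temperature": 0.0055, "ammonia": 0.0058, "fattening_day": 0.0325,
}


def final_model_spec() -> ModelSpec:
    """The final subset ARMAX(24, 24) structure: active AR and MA lags
    {1, 2, 22, 23, 24}, four harmonic pairs, temperature, ammonia and
    fattening day as contemporaneous regressors."""
    return ModelSpec(
        ar_lags=(1, 2, 22, 23, 24),
        ma_lags=(1, 2, 22, 23, 24),
        regressors=tuple(TABLE2_ETA.keys()),
        intercept=True,
    )


def truth_parameters(mu: float = 5.0, sigma2: float = 1.0) -> ParameterSet:
    """Published coefficients as a ParameterSet.

    The intercept and innovation variance were not published; defaults are
    mu = 5 (consumption units) and sigma^2 = 1.
    """
    return ParameterSet(
        mu=mu,
        phi=dict(TABLE1_PHI),
        theta=dict(TABLE1_THETA),
        eta=dict(TABLE2_ETA),
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentConfig:
    """Outdoor/indoor climate generator settings (continental inland site).

    Temperature (deg C) = annual sinusoid (period 8760 h, peak mid-July)
    + diurnal sinusoid (period 24 h, peak 15:00) + AR(1) noise with the given
    marginal SD.  Ammonia (ppm) = baseline + coupling * (temperature - annual
    mean) + white noise, floored at 0; the coupling is negative because summer
    ventilation lowers in-barn ammonia.
    """

    annual_mean: float = 13.0
    annual_amplitude: float = 8.0
    diurnal_amplitude: float = 4.0
    noise_ar: float = 0.6
    noise_sd: float = 1.2
    ammonia_baseline: float = 14.0
    ammonia_temp_slope: float = -0.35
    ammonia_noise_sd: float = 1.2
    humidity_mean: float = 65.0
    humidity_sd: float = 8.0
    co2_mean: float = 1500.0
    co2_sd: float = 250.0

    def validate(self) -> None:
        vals = asdict(self)
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("non-finite environment configuration value")
        for name in ("annual_amplitude", "diurnal_amplitude", "noise_sd",
                     "ammonia_noise_sd", "humidity_sd", "co2_sd"):
            if vals[name] < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.noise_ar < 1:
            raise ValueError("noise_ar must lie strictly inside (-1, 1)")


def simulate_environment(
    n_hours: int,
    start,
    cfg: EnvironmentConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Hourly covariate table (temperature, ammonia, humidity, co2)."""
    if n_hours < 1:
        raise ValueError("n_hours must be >= 1")
    cfg = cfg or EnvironmentConfig()
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = pd.date_range(pd.Timestamp(start), periods=n_hours, freq="h")
    # annual component at daily resolution (peak mid-July, day 196), so the
    # within-day pattern is carried entirely by the diurnal term
    annual = cfg.annual_mean + cfg.annual_amplitude * np.cos(
        2 * np.pi * (idx.dayofyear - 196) / 365.0
    )
    diurnal = cfg.diurnal_amplitude * np.cos(2 * np.pi * (idx.hour - 15) / 24.0)
    # AR(1) noise with stationary marginal SD = noise_sd
    innov_sd = cfg.noise_sd * math.sqrt(1 - cfg.noise_ar**2)
    eps = rng.normal(0.0, 1.0, size=n_hours)
    z = np.empty(n_hours)
    z[0] = cfg.noise_sd * eps[0]
    for t in range(1, n_hours):
        z[t] = cfg.noise_ar * z[t - 1] + innov_sd * eps[t]
    temperature = np.asarray(annual + diurnal) + z
    ammonia = (
        cfg.ammonia_baseline
        + cfg.ammonia_temp_slope * (temperature - cfg.annual_mean)
        + rng.normal(0.0, cfg.ammonia_noise_sd, size=n_hours)
    )
    ammonia = np.maximum(ammonia, 0.0)
    humidity = np.clip(rng.normal(cfg.humidity_mean, cfg.humidity_sd, size=n_hours), 5.0, 100.0)
    co2 = np.maximum(rng.normal(cfg.co2_mean, cfg.co2_sd, size=n_hours), 350.0)
    return pd.DataFrame(
        {"temperature": temperature, "ammonia": ammonia, "humidity": humidity, "co2": co2},
        index=idx,
    )


def simulate_pig_counts(
    n_start: int,
    mortality_total: float,
    n_hours: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Non-increasing hourly pig-count vector.

    Each pig independently dies with probability ``mortality_total``, at a
    time uniform over the batch, so the expected final count is
    n_start * (1 - mortality_total).
    """
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    if not 0 <= mortality_total < 1:
        raise ValueError("mortality_total must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.full(n_hours, n_start, dtype=int)
    n_deaths = rng.binomial(n_start, mortality_total)
    if n_deaths:
        times = rng.integers(0, n_hours, size=n_deaths)
        for t in times:
            counts[t:] -= 1
    return counts


# ---------------------------------------------------------------------------
# consumption profiles
# ---------------------------------------------------------------------------

#: farm-realistic calibration defaults (L/pig/day)
FIRST_WEEK_LPD = 2.35
PLATEAU_LPD = 8.05
TREND_RAMP_UP_DAYS = 75
END_RAMP_DAYS = 3


def daily_total_curve(day, start_lpd: float = FIRST_WEEK_LPD, plateau_lpd: float = PLATEAU_LPD,
                      ramp_up_days: int = TREND_RAMP_UP_DAYS):
    """Saturating daily-intake trend: linear rise reaching ``plateau_lpd`` at
    fattening day ``ramp_up_days``, flat thereafter.

    The day-1 level is solved so the mean over fattening days 1..7 equals
    ``start_lpd``, and the plateau is attained exactly within a standard
    15-week batch.  The end-of-batch ramp-down is applied separately (it
    depends on batch length).
    """
    d = np.asarray(day, dtype=float)
    frac7 = np.minimum(1.0, np.arange(7) / (ramp_up_days - 1)).mean()
    L0 = (start_lpd - plateau_lpd * frac7) / (1 - frac7)
    frac = np.minimum(1.0, (d - 1) / (ramp_up_days - 1))
    return L0 + (plateau_lpd - L0) * frac


_SHAPE_HOURS = np.arange(24.0)


def diurnal_shape() -> np.ndarray:
    """Fraction of the daily intake consumed in each clock hour (sums to 1).

    Morning bump centred ~10 h, dominant late-afternoon peak at 16-17 h,
    near-zero overnight; drinking starts around 5-6 h.
    """
    h = _SHAPE_HOURS
    morning = 0.32 * np.exp(-0.5 * ((h - 10.0) / 2.2) ** 2)
    evening = 0.58 * np.exp(-0.5 * ((h - 16.8) / 1.6) ** 2)
    daylight = 0.035 * ((h >= 6) & (h <= 21))
    night = 0.0015
    g = morning + evening + daylight + night
    return g / g.sum()


def mean_consumption_profile(hour_index, fattening_day, covariates=None, mode: str = "farm-realistic",
                             params: ParameterSet | None = None) -> np.ndarray:
    """Expected consumption (mL/pig/h) at the given hours/days.

    ``model-truth`` evaluates the linear predictor mu + harmonics + eta ·
    covariates with the supplied parameters (may be negative; used for
    estimator validation only).  ``farm-realistic`` evaluates the calibrated
    non-negative trend x diurnal-shape product.
    """
    h = np.asarray(hour_index) % 24
    d = np.asarray(fattening_day)
    if mode == "model-truth":
        params = params or truth_parameters()
        H = harmonic_design(h, n_harmonics=4)
        out = np.full(h.shape, params.mu, dtype=float)
        for col in H.columns:
            out += params.eta.get(col, 0.0) * H[col].to_numpy()
        out += params.eta.get("fattening_day", 0.0) * d
        for name, coef in params.eta.items():
            if name in H.columns or name == "fattening_day":
                continue
            if covariates is None or name not in covariates:
                raise KeyError(f"covariate '{name}' required by model-truth profile")
            out += coef * np.asarray(covariates[name], dtype=float)
        return out
    if mode == "farm-realistic":
        g = diurnal_shape()
        return daily_total_curve(d) * g[h.astype(int)] * 1000.0
    raise ValueError(f"unknown generator mode '{mode}'")


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------


@dataclass
class CorruptionRates:
    """Per-hour fault probabilities."""

    negative: float = 0.0299
    extreme: float = 0.0449
    consecutive: float = 0.005
    missing: float = 0.01

    def validate(self):
        for name, v in asdict(self).items():
            if not 0 <= v <= 1:
                raise ValueError(f"corruption rate {name} must be in [0, 1]")

    @classmethod
    def from_outlier_rate(cls, outlier_rate: float = 0.0748, **kw) -> "CorruptionRates":
        """Split a total detectable-outlier rate 60/40 into extreme/negative."""
        return cls(negative=0.4 * outlier_rate, extreme=0.6 * outlier_rate, **kw)

    @classmethod
    def none(cls) -> "CorruptionRates":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class BatchConfig:
    """Settings for one simulated barn x batch."""

    start: str = "2021-01-04"
    duration_weeks: int = 15
    n_start: int = 690
    mortality_total: float = 0.0339
    mode: str = "farm-realistic"
    start_lpd: float = FIRST_WEEK_LPD
    plateau_lpd: float = PLATEAU_LPD
    corruption: CorruptionRates = field(default_factory=CorruptionRates)
    non_drinking_rate: float = 0.074
    # multiplicative noise for a ~690-pig barn aggregate: individual-pig
    # variation largely averages out, leaving ~10% hourly and a few percent
    # day-to-day dispersion in the total
    noise_log_sd: float = 0.10
    noise_log_ar: float = 0.6
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    seed: int = 0
    barn_id: str = "barn1"
    batch_id: str = "batch1"

    def validate(self):
        if self.duration_weeks <= 0:
            raise ValueError("duration_weeks must be > 0")
        if not 0 <= self.mortality_total < 1:
            raise ValueError("mortality_total must be in [0, 1)")
        if self.mode not in {"farm-realistic", "model-truth"}:
            raise ValueError(f"unknown generator mode '{self.mode}'")
        if not 0 <= self.non_drinking_rate < 1:
            raise ValueError("non_drinking_rate must be in [0, 1)")
        self.corruption.validate()

    @property
    def n_hours(self) -> int:
        return self.duration_weeks * 7 * 24


@dataclass
class SimulatedBatch:
    """Raw 20-min readings, clean hourly ground truth and the fault ledger."""

    raw: pd.DataFrame
    clean: HourlySeries
    faults: pd.DataFrame
    config: BatchConfig


READING_COLUMNS = ("timestamp", "barn_id", "batch_id", "usage", "volume_l",
                   "pig_count", "temperature", "ammonia")


def _farm_clean_consumption(cfg: BatchConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_hours
    hours = np.arange(n)
    days = 1 + hours // 24
    base = daily_total_curve(days, cfg.start_lpd, cfg.plateau_lpd) * diurnal_shape()[hours % 24] * 1000.0
    # lognormal AR(1) multiplicative noise, unit mean
    a, s = cfg.noise_log_ar, cfg.noise_log_sd
    eps = rng.normal(0.0, 1.0, size=n)
    z = np.empty(n)
    z[0] = s * eps[0]
    isd = s * math.sqrt(1 - a * a)
    for t in range(1, n):
        z[t] = a * z[t - 1] + isd * eps[t]
    out = base * np.exp(z - 0.5 * s * s)
    # sharp end-of-batch decline: linear ramp to zero over the final days
    ramp_h = END_RAMP_DAYS * 24
    ramp = np.linspace(1.0, 0.0, ramp_h, endpoint=False)
    out[-ramp_h:] *= ramp
    return out


def simulate_batch(cfg: BatchConfig, model: tuple | None = None) -> SimulatedBatch:
    """Simulate one barn x batch.

    ``model`` optionally overrides the (spec, params) pair used in
    model-truth mode; defaults to the published final model with unit
    innovation SD.  Clean series = mean profile + noise; raw readings = the
    clean series split to exact 20-min cadence plus injected corruption.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_hours
    idx = pd.date_range(pd.Timestamp(cfg.start), periods=n, freq="h")
    env = simulate_environment(n, cfg.start, cfg.environment, rng)
    pigs = simulate_pig_counts(cfg.n_start, cfg.mortality_total, n, rng)
    days = 1 + np.arange(n) // 24

    truth = None
    if cfg.mode == "model-truth":
        if model is None:
            spec, params = final_model_spec(), truth_parameters()
        else:
            spec, params = model
        check_stationary_invertible(params)
        X = harmonic_design(idx.hour.to_numpy(), n_harmonics=4)
        X["temperature"] = env["temperature"].to_numpy()
        X["ammonia"] = env["ammonia"].to_numpy()
        X["fattening_day"] = days.astype(float)
        cons = simulate_armax(spec, params, X, n, burn_in=2000, seed=rng)
        truth = {"spec": {"ar_lags": spec.ar_lags, "ma_lags": spec.ma_lags,
                          "regressors": spec.regressors},
                 "params": {"mu": params.mu, "phi": params.phi, "theta": params.theta,
                            "eta": params.eta, "sigma2": params.sigma2}}
    else:
        cons = _farm_clean_consumption(cfg, rng)

    data = pd.DataFrame(
        {
            "consumption": cons,
            "pig_count": pigs,
            "temperature": env["temperature"].to_numpy(),
            "ammonia": env["ammonia"].to_numpy(),
            "humidity": env["humidity"].to_numpy(),
            "co2": env["co2"].to_numpy(),
            "fattening_day": days,
            "missing": False,
        },
        index=idx,
    )
    clean = HourlySeries(
        data=data,
        barn_id=cfg.barn_id,
        batch_id=cfg.batch_id,
        provenance={"seed": cfg.seed, "mode": cfg.mode, "truth": truth,
                    "generator": "pigwater.synthetic.simulate_batch"},
    )

    # split each hour into 3 exact 20-min readings
    total_l = cons * pigs / 1000.0  # barn-level L/h
    props = rng.dirichlet(np.full(3, 6.0), size=n)
    volumes = (props * total_l[:, None]).ravel()
    ts = np.repeat(idx.values, 3) + np.tile(
        np.array([0, 20, 40], dtype="timedelta64[m]"), n
    )
    raw = pd.DataFrame(
        {
            "timestamp": ts,
            "barn_id": cfg.barn_id,
            "batch_id": cfg.batch_id,
            "usage": "drinking",
            "volume_l": volumes,
            "pig_count": np.repeat(pigs, 3),
            "temperature": np.repeat(env["temperature"].to_numpy(), 3),
            "ammonia": np.repeat(env["ammonia"].to_numpy(), 3),
        }
    )

    # non-drinking usage channels (cooling/cleaning), as extra records
    if cfg.non_drinking_rate > 0:
        n_extra = int(round(len(raw) * cfg.non_drinking_rate / (1 - cfg.non_drinking_rate)))
        pick = rng.integers(0, len(raw), size=n_extra)
        extra = raw.iloc[pick].copy()
        extra["usage"] = rng.choice(["cooling", "cleaning"], size=n_extra, p=[0.7, 0.3])
        extra["volume_l"] = rng.gamma(2.0, 30.0, size=n_extra)
        raw = pd.concat([raw, extra], ignore_index=True)
        raw = raw.sort_values(["timestamp", "usage"], kind="stable").reset_index(drop=True)

    raw, faults = corrupt_readings(raw, cfg.corruption, rng)
    return SimulatedBatch(raw=raw, clean=clean, faults=faults, config=cfg)


def corrupt_readings(
    readings: pd.DataFrame,
    rates: CorruptionRates,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Inject sensor faults into drinking readings; return (readings, ledger).

    Fault kinds (disjoint sets of clock hours):

    - ``negative``: one reading made negative enough that the hourly sum < 0;
    - ``extreme``: one reading inflated so the hourly per-pig total exceeds
      the 10 L/pig/h cleaning threshold by construction;
    - ``consecutive``: one hour's volume doubled into the previous hour and
      then zeroed (the undetectable "sums of consecutive hours" error);
    - ``missing``: one of the hour's sub-readings dropped.

    The ledger records (timestamp, barn_id, batch_id, kind) per faulted hour.
    """
    rates.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = readings.copy()
    ledger_rows = []
    drink = out[out["usage"] == "drinking"]
    hour = drink["timestamp"].dt.floor("h")
    groups = drink.groupby([drink["barn_id"], drink["batch_id"], hour]).indices
    keys = list(groups.keys())
    n_hours_total = len(keys)
    pool = list(range(n_hours_total))
    rng.shuffle(pool)
    pool_set = set(pool)

    def take(rate):
        k = rng.binomial(n_hours_total, rate)
        chosen = []
        while pool and len(chosen) < k:
            c = pool.pop()
            pool_set.discard(c)
            chosen.append(c)
        return chosen

    drop_rows = []
    for i in take(rates.negative):
        barn, batch, h = keys[i]
        rows = drink.index[groups[keys[i]]]
        s = out.loc[rows, "volume_l"].sum()
        j = rows[int(rng.integers(len(rows)))]
        out.loc[j, "volume_l"] -= s + 0.5 + rng.exponential(1.0)
        ledger_rows.append((h, barn, batch, "negative"))
    for i in take(rates.extreme):
        barn, batch, h = keys[i]
        rows = drink.index[groups[keys[i]]]
        j = rows[int(rng.integers(len(rows)))]
        pigs = out.loc[j, "pig_count"]
        out.loc[j, "volume_l"] += (10.5 + rng.exponential(2.0)) * max(pigs, 1)
        ledger_rows.append((h, barn, batch, "extreme"))
    # consecutive-hour sums: need hour i and its successor both untouched
    k_consec = rng.binomial(n_hours_total, rates.consecutive)
    key_index = {k: i for i, k in enumerate(keys)}
    placed = 0
    attempts = 0
    while placed < k_consec and attempts < 20 * max(k_consec, 1) and pool:
        attempts += 1
        i = pool[-1]
        barn, batch, h = keys[i]
        nxt = (barn, batch, h + pd.Timedelta(hours=1))
        inext = key_index.get(nxt)
        if inext is None or inext not in pool_set or inext == i:
            rng.shuffle(pool)
            continue
        pool.pop()
        pool_set.discard(i)
        pool.remove(inext)
        pool_set.discard(inext)
        rows_next = drink.index[groups[nxt]]
        vol_next = out.loc[rows_next, "volume_l"].sum()
        rows_this = drink.index[groups[keys[i]]]
        out.loc[rows_this[0], "volume_l"] += vol_next
        out.loc[rows_next, "volume_l"] = 0.0
        ledger_rows.append((h, barn, batch, "consecutive"))
        ledger_rows.append((nxt[2], barn, batch, "consecutive"))
        placed += 1
    for i in take(rates.missing):
        barn, batch, h = keys[i]
        rows = drink.index[groups[keys[i]]]
        drop_rows.append(rows[int(rng.integers(len(rows)))])
        ledger_rows.append((h, barn, batch, "missing"))
    if drop_rows:
        out = out.drop(index=drop_rows)
    ledger = pd.DataFrame(ledger_rows, columns=["timestamp", "barn_id", "batch_id", "kind"])
    return out.reset_index(drop=True), ledger.sort_values("timestamp").reset_index(drop=True)


def simulate_farm(
    n_barns: int = 6,
    n_batches: int = 5,
    seed: int = 0,
    start: str = "2020-12-21",
    **batch_kwargs,
) -> list:
    """Simulate ``n_barns`` x ``n_batches`` batches (sequential in time per
    barn, one week of downtime between batches)."""
    root = np.random.default_rng(seed)
    batches = []
    for b in range(n_barns):
        t0 = pd.Timestamp(start)
        for k in range(n_batches):
            cfg = BatchConfig(
                start=str(t0),
                n_start=int(root.integers(660, 731)),
                seed=int(root.integers(0, 2**31 - 1)),
                barn_id=f"barn{b + 1}",
                batch_id=f"batch{k + 1}",
                **batch_kwargs,
            )
            batches.append(simulate_batch(cfg))
            t0 = t0 + pd.Timedelta(weeks=cfg.duration_weeks + 1)
    return batches
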