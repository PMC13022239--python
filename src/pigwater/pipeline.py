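"""End-to-end orchestration: simulate -> clean -> design -> fit -> prune ->
refit -> diagnose -> forecast, as a configurable, logged, reproducible run.

A run writes a directory of delimited-text artifacts (cleaned series, score
or coefficient tables, forecasts, diagnostics, log) plus the fully resolved
configuration, so every stage can be re-run or audited from files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .armax import FittedModel, ModelSpec, ParameterSet, fit_ml, prune_coefficients, wald_tests
from .design import COVARIATE_LABELS, design_matrix
from .diagnostics import residual_report
from .forecasting import forecast_h, rolling_one_step
from .preprocessing import clean_readings, split_train_test
from .series import HourlySeries
from .synthetic import CorruptionRates, simulate_farm

logger = logging.getLogger(__name__)

ARTIFACTS = ("config.yaml", "cleaning_report.csv", "coefficients.csv",
             "fit.json", "forecasts.csv", "diagnostics.json")


@dataclass
class RunConfig:
    """Fully explicit settings for one pipeline run.

    Analysis defaults mirror the final published analysis: 10 L/pig/h
    cleaning threshold, four harmonics, temperature/ammonia/fattening-day
    covariates, pruning at alpha = 0.05, 95% intervals, lag-24 diagnostics.
    """

    # simulation (used when input_path is None)
    n_barns: int = 2
    n_batches: int = 2
    duration_weeks: int = 8
    mode: str = "farm-realistic"
    corruption: bool = True
    seed: int = 0
    input_path: str | None = None
    # cleaning
    threshold: float = 10_000.0
    split_policy: str = "last-batch-per-barn"
    # design
    n_harmonics: int = 4
    covariates: tuple = ("temperature", "ammonia")
    # model
    ar_lags: tuple = (1, 2, 22, 23, 24)
    ma_lags: tuple = (1, 2, 22, 23, 24)
    prune: bool = True
    prune_alpha: float = 0.05
    # concatenated training series are separated by this many missing hours
    concat_gap_hours: int = 48
    # forecasting / diagnostics
    forecast_horizon: int = 168
    forecast_mode: str = "onestep"  # onestep | multistep
    level: float = 0.95
    lb_lags: int = 24
    out_dir: str = "run"

    def validate(self) -> None:
        if self.forecast_mode not in {"onestep", "multistep"}:
            raise ValueError(f"unknown forecast mode '{self.forecast_mode}'")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.prune_alpha < 1:
            raise ValueError("prune_alpha must be in (0, 1)")
        if self.n_harmonics < 1 or self.lb_lags < 1 or self.forecast_horizon < 1:
            raise ValueError("n_harmonics, lb_lags and forecast_horizon must be >= 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["ar_lags"] = list(self.ar_lags)
        d["ma_lags"] = list(self.ma_lags)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "ar_lags", "ma_lags"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _design(series: HourlySeries, cfg: RunConfig) -> pd.DataFrame:
    return design_matrix(series, n_harmonics=cfg.n_harmonics, covariates=cfg.covariates)


def _concat_training(train, cfg: RunConfig):
    """Stack training series with a block of missing hours between them, so
    the filter treats segments as (approximately) independent."""
    ys, Xs = [], []
    gap = cfg.concat_gap_hours
    for i, s in enumerate(train):
        y = s.consumption()
        X = _design(s, cfg)
        y = np.where(s.data["missing"].to_numpy(bool), np.nan, y)
        ys.append(y)
        Xs.append(X)
        if i < len(train) - 1:
            ys.append(np.full(gap, np.nan))
            Xs.append(pd.DataFrame(0.0, index=range(gap), columns=X.columns))
    return np.concatenate(ys), pd.concat(Xs, ignore_index=True)


def _fitted_to_dict(fitted: FittedModel) -> dict:
    a, P = fitted.filter_state
    return {
        "spec": {"ar_lags": list(fitted.spec.ar_lags), "ma_lags": list(fitted.spec.ma_lags),
                 "regressors": list(fitted.spec.regressors), "intercept": fitted.spec.intercept},
        "params": {"mu": fitted.params.mu,
                   "phi": {str(k): v for k, v in fitted.params.phi.items()},
                   "theta": {str(k): v for k, v in fitted.params.theta.items()},
                   "eta": dict(fitted.params.eta),
                   "sigma2": fitted.params.sigma2},
        "se": dict(fitted.se),
        "loglik": fitted.loglik, "nobs": fitted.nobs,
        "aic": fitted.aic, "aicc": fitted.aicc, "bic": fitted.bic,
        "converged": fitted.converged, "n_iter": fitted.n_iter,
        "min_root_modulus": fitted.min_root_modulus,
        "filter_state": {"a": a.tolist(), "P": P.tolist()},
        "package_version": __version__,
    }


def load_fitted(path) -> FittedModel:
    """Rebuild a FittedModel (without residuals) from a fit.json artifact."""
    with open(path) as fh:
        d = json.load(fh)
    spec = ModelSpec(ar_lags=tuple(d["spec"]["ar_lags"]), ma_lags=tuple(d["spec"]["ma_lags"]),
                     regressors=tuple(d["spec"]["regressors"]), intercept=d["spec"]["intercept"])
    pr = d["params"]
    params = ParameterSet(mu=pr["mu"], phi={int(k): v for k, v in pr["phi"].items()},
                          theta={int(k): v for k, v in pr["theta"].items()},
                          eta=dict(pr["eta"]), sigma2=pr["sigma2"])
    return FittedModel(
        spec=spec, params=params, cov=np.empty((0, 0)), se=d["se"],
        loglik=d["loglik"], nobs=d["nobs"], aic=d["aic"], aicc=d["aicc"], bic=d["bic"],
        residuals=np.empty(0), std_residuals=np.empty(0), converged=d["converged"],
        n_iter=d["n_iter"], min_root_modulus=d["min_root_modulus"],
        near_boundary=False,
        filter_state=(np.asarray(d["filter_state"]["a"]), np.asarray(d["filter_state"]["P"])),
    )


def coefficient_frame(fitted: FittedModel) -> pd.DataFrame:
    """Coefficient table (term, description, coefficient, SE, z, p) in the
    published layout: ARMA terms first, then harmonics and covariates."""
    tab = wald_tests(fitted).reset_index()
    desc = []
    for term in tab["term"]:
        if term.startswith("ar"):
            desc.append(f"AR lag {term[2:]}")
        elif term.startswith("ma"):
            desc.append(f"MA lag {term[2:]}")
        elif term == "mu":
            desc.append("Intercept")
        elif term.startswith("S"):
            desc.append(f"Sine (period {24 // int(term[1:])} h)")
        elif term.startswith("C"):
            desc.append(f"Cosine (period {24 // int(term[1:])} h)")
        elif term == "temperature":
            desc.append("Outside temperature")
        elif term == "ammonia":
            desc.append("Ammonia concentration")
        elif term == "fattening_day":
            desc.append("Fattening day")
        else:
            desc.append(term)
    tab.insert(1, "description", desc)
    tab["term"] = [COVARIATE_LABELS.get(t, t) for t in tab["term"]]
    arma = tab[tab["description"].str.startswith(("AR ", "MA "))]
    rest = tab[~tab["description"].str.startswith(("AR ", "MA "))]
    return pd.concat([arma, rest], ignore_index=True)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error is re-raised with the stage name; artifacts written by
    earlier stages are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pigwater")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    stage = "simulate"
    try:
        # -- simulate or load ------------------------------------------------
        if config.input_path:
            readings = pd.read_csv(config.input_path, parse_dates=["timestamp"])
        else:
            corruption = {} if config.corruption else {"corruption": CorruptionRates.none()}
            batches = simulate_farm(n_barns=config.n_barns, n_batches=config.n_batches,
                                    duration_weeks=config.duration_weeks, mode=config.mode,
                                    seed=config.seed, **corruption)
            readings = pd.concat([b.raw for b in batches], ignore_index=True)
            readings.to_csv(out / "raw_readings.csv", index=False)
            pd.concat([b.faults for b in batches], ignore_index=True).to_csv(
                out / "fault_ledger.csv", index=False)
        logger.info("stage simulate: %d raw records", len(readings))

        # -- clean -----------------------------------------------------------
        stage = "preprocess"
        series_list, creport = clean_readings(readings, threshold=config.threshold)
        creport.to_frame().to_csv(out / "cleaning_report.csv", index=False)
        cleaned_dir = out / "cleaned"
        cleaned_dir.mkdir(exist_ok=True)
        for s in series_list:
            s.to_csv(cleaned_dir / f"{s.barn_id}_{s.batch_id}.csv")
        train, test = split_train_test(series_list, policy=config.split_policy)
        (out / "split.json").write_text(json.dumps(
            {"train": [s.key() for s in train], "test": [s.key() for s in test]}, indent=2))

        # -- design + fit ----------------------------------------------------
        stage = "design"
        y, X = _concat_training(train, config)
        stage = "fit"
        spec = ModelSpec(ar_lags=config.ar_lags, ma_lags=config.ma_lags,
                         regressors=tuple(X.columns), intercept=True)
        fitted = fit_ml(spec, y, X)
        logger.info("stage fit: loglik %.2f AIC %.2f converged %s",
                    fitted.loglik, fitted.aic, fitted.converged)
        pruned_terms = []
        if config.prune:
            new_spec = prune_coefficients(fitted, alpha=config.prune_alpha)
            if new_spec != spec:
                pruned_terms = sorted(set(spec.param_names()) - set(new_spec.param_names()))
                logger.info("stage prune: dropped %s", pruned_terms)
                fitted = fit_ml(new_spec, y, X)
        coefficient_frame(fitted).to_csv(out / "coefficients.csv", index=False)
        fit_dict = _fitted_to_dict(fitted)
        fit_dict["pruned_terms"] = pruned_terms
        (out / "fit.json").write_text(json.dumps(fit_dict, indent=2))

        # -- diagnostics -----------------------------------------------------
        stage = "diagnose"
        diag = residual_report(fitted, y, lags=config.lb_lags, seed=config.seed)
        (out / "diagnostics.json").write_text(json.dumps(diag.to_dict(), indent=2))
        (out / "diagnostics.txt").write_text(diag.summary() + "\n")

        # -- forecast --------------------------------------------------------
        stage = "forecast"
        rows = []
        for s in test:
            Xt = _design(s, config)
            yt = s.consumption()
            if config.forecast_mode == "onestep":
                fc = rolling_one_step(fitted, yt, Xt, level=config.level)
            else:
                h = min(config.forecast_horizon, s.n_hours)
                fc = forecast_h_from_start(fitted, yt, Xt, h, level=config.level)
            df = fc.to_frame()
            df.insert(0, "timestamp", s.data.index[: len(df)])
            df.insert(1, "series", s.key())
            rows.append(df)
            logger.info("stage forecast: %s rmse %.2f", s.key(), fc.rmse or float("nan"))
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(out / "forecasts.csv", index=False)
        else:
            (out / "forecasts.csv").write_text("timestamp,series,forecast,se,lo,hi\n")
        logger.info("run complete: %s", out)
        return out
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(fh)
        fh.close()


def forecast_h_from_start(fitted: FittedModel, y, X, h: int, level: float = 0.95,
                          warmup_fraction: float = 0.5):
    """Fixed-origin multi-step forecast over the tail of a held-out series:
    filter the first part as history, forecast ``h`` steps, score against the
    realised values."""
    from .forecasting import forecast_series

    n = len(y)
    origin = max(int(n * warmup_fraction), 1)
    h = min(h, n - origin)
    fc = forecast_series(fitted, y[:origin], X.iloc[:origin], X.iloc[origin : origin + h], h,
                         level=level)
    return fc.with_actual(np.asarray(y[origin : origin + h], dtype=float))


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    missing = [a for a in ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory; missing artifacts: {missing}")
    cfg = RunConfig.from_yaml(run_dir / "config.yaml")
    lines = [f"pigwater run report — {run_dir}", "=" * 60, ""]
    lines.append("Cleaning")
    lines.append(pd.read_csv(run_dir / "cleaning_report.csv").to_string(index=False))
    lines.append("")
    fit = json.loads((run_dir / "fit.json").read_text())
    spec = fit["spec"]
    lines.append(f"Model: subset ARMAX, AR lags {spec['ar_lags']}, MA lags {spec['ma_lags']}, "
                 f"regressors {spec['regressors']}")
    lines.append(f"  log-likelihood {fit['loglik']:.2f}  nobs {fit['nobs']}  "
                 f"AIC {fit['aic']:.2f}  AICc {fit['aicc']:.2f}  BIC {fit['bic']:.2f}")
    lines.append(f"  converged: {fit['converged']}  min root modulus {fit['min_root_modulus']:.4f}")
    lines.append("")
    lines.append("Coefficients")
    lines.append(pd.read_csv(run_dir / "coefficients.csv").round(4).to_string(index=False))
    if fit.get("pruned_terms"):
        lines.append("")
        lines.append(f"Pruned terms (p > {cfg.prune_alpha}): {fit['pruned_terms']}")
    lines.append("")
    lines.append((run_dir / "diagnostics.txt").read_text().rstrip())
    lines.append("")
    fc_path = run_dir / "forecasts.csv"
    fc = pd.read_csv(fc_path)
    if fc.empty or "actual" not in fc.columns:
        lines.append("Forecasts: not evaluated (empty test set)")
    else:
        lines.append("Forecast accuracy (per held-out series)")
        for key, sub in fc.groupby("series"):
            ok = sub[["forecast", "actual"]].dropna()
            r = float(np.sqrt(np.mean((ok["forecast"] - ok["actual"]) ** 2)))
            inside = ((sub["actual"] >= sub["lo"]) & (sub["actual"] <= sub["hi"])).mean()
            lines.append(f"  {key}: RMSE {r:.2f} mL/pig/h, {cfg.level:.0%} interval coverage "
                         f"{inside:.1%} over {len(sub)} h")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
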