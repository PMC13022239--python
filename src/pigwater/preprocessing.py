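"""Cleaning and partitioning of raw water-meter readings.

The cleaning rules, applied in order:

1. drop cooling/cleaning usage records (drinking only);
2. aggregate 20-min readings into left-closed clock-hour bins, flagging any
   hour with a missing sub-reading;
3. drop hours that cannot be paired with a positive pig count ("unpaired");
4. divide barn totals by the pig count and convert to mL/pig/h;
5. mark hours above 10 L/pig/h (strictly > 10,000 mL) or negative as missing.

Removed records become missing hours rather than being deleted, preserving
the hourly grid the state-space likelihood expects; every input record is
retained or attributed to exactly one removal rule in the CleaningReport.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import HourlySeries

logger = logging.getLogger(__name__)

USAGE_TYPES = frozenset({"drinking", "cooling", "cleaning"})
DEFAULT_THRESHOLD = 10_000.0  # mL/pig/h  (= 10 L/pig/h)
READINGS_PER_HOUR = 3


@dataclass
class CleaningReport:
    """Counts removed by each rule, at reading level (usage filter) and at
    hour level (everything downstream of aggregation).

    Conservation: ``input_records = removed_usage + retained_records`` and
    ``hours_total = hours_incomplete + hours_unpaired + hours_extreme +
    hours_negative + hours_usable``.
    """

    input_records: int = 0
    removed_usage: int = 0
    hours_total: int = 0
    hours_incomplete: int = 0  # absent hour or missing sub-reading
    hours_unpaired: int = 0    # no positive pig count
    hours_extreme: int = 0     # > threshold mL/pig/h
    hours_negative: int = 0
    hours_usable: int = 0

    def add(self, rule: str, count: int) -> None:
        setattr(self, rule, getattr(self, rule) + int(count))

    @property
    def retained_records(self) -> int:
        return self.input_records - self.removed_usage

    @property
    def usage_fraction(self) -> float:
        return self.removed_usage / self.input_records if self.input_records else 0.0

    def hour_fraction(self, rule: str) -> float:
        return getattr(self, f"hours_{rule}") / self.hours_total if self.hours_total else 0.0

    def check_conservation(self) -> bool:
        rec_ok = self.removed_usage + self.retained_records == self.input_records
        hrs_ok = (self.hours_incomplete + self.hours_unpaired + self.hours_extreme
                  + self.hours_negative + self.hours_usable) == self.hours_total
        return rec_ok and hrs_ok

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "reading", "rule": "usage_type", "count": self.removed_usage,
             "fraction": self.usage_fraction},
            {"level": "reading", "rule": "retained", "count": self.retained_records,
             "fraction": 1 - self.usage_fraction},
        ]
        for rule in ("incomplete", "unpaired", "extreme", "negative", "usable"):
            rows.append({"level": "hour", "rule": rule,
                         "count": getattr(self, f"hours_{rule}"),
                         "fraction": self.hour_fraction(rule)})
        return pd.DataFrame(rows)


def filter_usage_type(readings: pd.DataFrame, report: CleaningReport | None = None):
    """Keep drinking records only; count cooling/cleaning removals."""
    unknown = set(readings["usage"].unique()) - USAGE_TYPES
    if unknown:
        raise ValueError(f"unknown usage-type label(s): {sorted(unknown)}")
    keep = readings["usage"] == "drinking"
    removed = int((~keep).sum())
    if report is not None:
        report.input_records = report.input_records or len(readings)
        report.add("removed_usage", removed)
    out = readings[keep].copy()
    if out.empty:
        logger.warning("no drinking records remain after usage-type filtering")
    return out


def aggregate_hourly(readings: pd.DataFrame, expected_per_hour: int = READINGS_PER_HOUR) -> pd.DataFrame:
    """Sum sub-hourly drinking volumes into clock-hour bins.

    Hour h covers [h:00, h+1:00) local time.  Hours with fewer than
    ``expected_per_hour`` sub-readings — and hours absent altogether from the
    interior of the record — are flagged missing.  A duplicated reading for
    the same sub-interval raises an error naming the timestamp.
    """
    df = readings.sort_values("timestamp", kind="stable")
    dup = df.duplicated(subset=["barn_id", "batch_id", "timestamp"])
    if dup.any():
        t = df.loc[dup, "timestamp"].iloc[0]
        raise ValueError(f"duplicate reading for interval starting {t}")
    hour = df["timestamp"].dt.floor("h")
    grouped = df.groupby([df["barn_id"], df["batch_id"], hour], sort=True)
    agg = grouped.agg(
        volume_l=("volume_l", "sum"),
        n_readings=("volume_l", "size"),
        pig_count=("pig_count", "min"),
        temperature=("temperature", "mean"),
        ammonia=("ammonia", "mean"),
    ).reset_index().rename(columns={"timestamp": "hour"})
    agg["missing"] = agg["n_readings"] < expected_per_hour
    # reindex each barn x batch onto its full hourly grid
    pieces = []
    for (barn, batch), sub in agg.groupby(["barn_id", "batch_id"]):
        grid = pd.date_range(sub["hour"].min(), sub["hour"].max(), freq="h")
        sub = sub.set_index("hour").reindex(grid)
        absent = sub["n_readings"].isna()
        sub.loc[absent, "missing"] = True
        sub["barn_id"] = barn
        sub["batch_id"] = batch
        pieces.append(sub.rename_axis("hour").reset_index())
    return pd.concat(pieces, ignore_index=True)


def normalize_per_pig(total_volume_l, pig_count):
    """Per-pig consumption in mL/pig/h: 1000 * volume / count.

    Elements with a non-positive or missing pig count return NaN (the
    "could not be paired" rule; the caller drops and reports them).
    """
    v = np.asarray(total_volume_l, dtype=float)
    c = np.asarray(pig_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1000.0 * v / c
    out = np.where(np.isfinite(c) & (c >= 1), out, np.nan)
    return out if out.ndim else float(out)


def remove_outliers(series: HourlySeries, threshold: float = DEFAULT_THRESHOLD,
                    report: CleaningReport | None = None) -> HourlySeries:
    """Mark hours strictly above ``threshold`` mL/pig/h, or negative, missing.

    The comparison is strict ("exceeding"): a value equal to the threshold is
    retained.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = series.data
    y = df["consumption"].to_numpy(dtype=float)
    already = df["missing"].to_numpy(bool)
    extreme = (~already) & (y > threshold)
    negative = (~already) & (y < 0)
    if report is not None:
        report.add("hours_extreme", extreme.sum())
        report.add("hours_negative", negative.sum())
    df.loc[extreme | negative, "missing"] = True
    df.loc[extreme | negative, "consumption"] = np.nan
    return series


def clean_readings(readings: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD):
    """Full cleaning pipeline: raw readings -> list of HourlySeries + report.

    One HourlySeries per barn x batch present in the input.
    """
    report = CleaningReport(input_records=len(readings))
    drink = filter_usage_type(readings, report)
    hourly = aggregate_hourly(drink)
    series_list = []
    for (barn, batch), sub in hourly.groupby(["barn_id", "batch_id"]):
        sub = sub.set_index("hour").sort_index()
        report.add("hours_total", len(sub))
        report.add("hours_incomplete", int(sub["missing"].sum()))
        unpaired = (~sub["missing"]) & ~(sub["pig_count"] >= 1)
        report.add("hours_unpaired", int(unpaired.sum()))
        sub.loc[unpaired, "missing"] = True
        cons = normalize_per_pig(sub["volume_l"].to_numpy(), sub["pig_count"].to_numpy())
        cons[sub["missing"].to_numpy(bool)] = np.nan
        data = pd.DataFrame(
            {
                "consumption": cons,
                "pig_count": sub["pig_count"].to_numpy(),
                "temperature": sub["temperature"].to_numpy(),
                "ammonia": sub["ammonia"].to_numpy(),
                "missing": sub["missing"].to_numpy(bool),
            },
            index=sub.index,
        )
        s = HourlySeries(data=data, barn_id=str(barn), batch_id=str(batch),
                         provenance={"cleaning_threshold": threshold})
        remove_outliers(s, threshold, report)
        series_list.append(s)
    report.hours_usable = report.hours_total - (
        report.hours_incomplete + report.hours_unpaired + report.hours_extreme + report.hours_negative
    )
    logger.info("cleaned %d records into %d series (%d usable hours)",
                report.input_records, len(series_list), report.hours_usable)
    return series_list, report


def split_train_test(series_set, policy: str = "last-batch-per-barn"):
    """Partition series into train/test sets.

    The default policy holds out exactly one batch per barn — the last by
    start time — mirroring a four-train/one-test split per barn.
    """
    series_set = list(series_set)
    if policy == "all-train":
        return series_set, []
    if policy != "last-batch-per-barn":
        raise ValueError(f"unknown split policy '{policy}'")
    by_barn = {}
    for s in series_set:
        by_barn.setdefault(s.barn_id, []).append(s)
    train, test = [], []
    for barn, group in by_barn.items():
        if len(group) < 2:
            raise ValueError(
                f"barn '{barn}' has a single batch; use policy='all-train' instead"
            )
        group = sorted(group, key=lambda s: s.start)
        train.extend(group[:-1])
        test.append(group[-1])
    logger.info("split: %d train / %d test series", len(train), len(test))
    return train, test
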