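"""The HourlySeries container: one barn x batch set of hourly records.

Consumption is stored in mL/pig/h on a complete hourly grid; hours removed by
cleaning (or never observed) are NaN with ``missing = True``, which is what
the exact-likelihood machinery expects (prediction without update, no
imputation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("consumption", "pig_count", "missing")


@dataclass
class HourlySeries:
    """Hourly consumption record set for one barn x batch.

    ``data`` is indexed by an hourly DatetimeIndex and holds at least
    ``consumption`` (mL/pig/h, NaN where missing), ``pig_count`` and the
    boolean ``missing`` mask, plus any covariate columns (``temperature`` in
    deg C, ``ammonia`` in ppm, ...).  ``fattening_day`` (days since batch
    start, 1-based) is derived from the index if not supplied.
    """

    data: pd.DataFrame
    barn_id: str = "barn1"
    batch_id: str = "batch1"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("HourlySeries.data must be indexed by a DatetimeIndex")
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"HourlySeries.data missing required column '{col}'")
        if df.index.has_duplicates:
            raise ValueError("duplicate hourly timestamps")
        if not df.index.is_monotonic_increasing:
            self.data = df = df.sort_index()
        if "fattening_day" not in df.columns:
            start = df.index[0]
            hours = ((df.index - start) / pd.Timedelta(hours=1)).astype(int)
            df["fattening_day"] = 1 + hours // 24

    # -- accessors ---------------------------------------------------------

    @property
    def n_hours(self) -> int:
        return len(self.data)

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    def consumption(self) -> np.ndarray:
        """Consumption vector (mL/pig/h) with NaN at missing hours."""
        y = self.data["consumption"].to_numpy(dtype=float).copy()
        y[self.data["missing"].to_numpy(bool)] = np.nan
        return y

    def hour_of_day(self) -> np.ndarray:
        return self.data.index.hour.to_numpy()

    def key(self) -> str:
        return f"{self.barn_id}/{self.batch_id}"

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "barn_id", self.barn_id)
        out.insert(1, "batch_id", self.batch_id)
        out.to_csv(path, index_label="timestamp")

    @classmethod
    def from_csv(cls, path) -> "HourlySeries":
        df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
        barn = str(df.pop("barn_id").iloc[0]) if "barn_id" in df else "barn1"
        batch = str(df.pop("batch_id").iloc[0]) if "batch_id" in df else "batch1"
        df["missing"] = df["missing"].astype(bool)
        return cls(data=df, barn_id=barn, batch_id=batch)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
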