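"""Medication and supplement dose log.

Doses are recorded as dated entries (drug or supplement, dose value,
unit). For analysis they are aligned to the blood-draw dates, either as
the dose recorded on the day of draw or as the mean dose over a +/- w
day window around each draw. Unrecorded doses are missing, not zero,
unless the caller opts into a missing-as-zero policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    key = " ".join(name.strip().casefold().split())
    if synonyms:
        key = synonyms.get(key, key)
    return key


@dataclass
class MedicationLog:
    """Dated dose entries plus the set of tracked medication names."""

    entries: pd.DataFrame  # columns: date, name, dose, unit, is_supplement
    medications: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.entries.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        if "unit" not in df:
            df["unit"] = "mg"
        if "is_supplement" not in df:
            df["is_supplement"] = False
        if (df["dose"].dropna() < 0).any():
            raise ValueError("doses must be non-negative")
        units = df.dropna(subset=["dose"]).groupby("name")["unit"].nunique()
        mixed = units[units > 1].index.tolist()
        if mixed:
            raise ValueError(f"inconsistent units within medication(s): {mixed}")
        self.entries = df
        if not self.medications:
            self.medications = sorted(df["name"].unique())

    @classmethod
    def from_csv(cls, path: str | Path) -> "MedicationLog":
        return cls(pd.read_csv(path))

    @classmethod
    def from_json(cls, path: str | Path) -> "MedicationLog":
        with open(path) as fh:
            return cls(pd.DataFrame(json.load(fh)))

    def to_csv(self, path: str | Path) -> None:
        out = self.entries.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    def dose_on(self, sample_date, window_days: int = 0) -> pd.Series:
        """Mean recorded dose per medication within +/- window_days of
        the sample date; missing where nothing was recorded."""
        day = pd.Timestamp(sample_date).normalize()
        lo = day - pd.Timedelta(days=window_days)
        hi = day + pd.Timedelta(days=window_days)
        win = self.entries[(self.entries["date"] >= lo) & (self.entries["date"] <= hi)]
        means = win.dropna(subset=["dose"]).groupby("name")["dose"].mean()
        return means.reindex(self.medications)

    def dose_matrix(self, sample_dates, window_days: int = 0) -> pd.DataFrame:
        """Medications x timepoints dose matrix aligned to sample dates."""
        cols = {pd.Timestamp(d).strftime("%Y-%m-%d"): self.dose_on(d, window_days)
                for d in sample_dates}
        return pd.DataFrame(cols)
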