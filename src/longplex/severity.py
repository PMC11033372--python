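"""Disease-severity scale and timeline.

The severity framework places a patient on a 1-10 scale across five
categories (mild, moderate, severe, very severe, extremely severe),
with the extremely severe category subdivided into grades A-E. Within
the extremely severe band, A is the *least* impaired grade and E the
most: a patient improving from extremely severe D to A moves up the
scale.

The literature defines the ordering of the scale but not a numeric
coding, so the mapping below is one admissible monotone choice and is
configurable. With only two observed grades (the common N-of-1
situation: a long run at one grade and a final improved sample),
Pearson correlations against the coding are invariant in magnitude to
the particular numbers chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("mild", "moderate", "severe", "very severe", "extremely severe")
SUBCLASSES = ("A", "B", "C", "D", "E")

#: Default numeric coding (higher = less impaired). Any strictly
#: monotone alternative may be passed to :meth:`SeverityGrade.numeric`.
DEFAULT_SCORES: dict[tuple[str, str | None], float] = {
    ("mild", None): 9.0,
    ("moderate", None): 7.0,
    ("severe", None): 5.0,
    ("very severe", None): 3.0,
    ("extremely severe", "A"): 2.0,
    ("extremely severe", "B"): 1.75,
    ("extremely severe", "C"): 1.5,
    ("extremely severe", "D"): 1.25,
    ("extremely severe", "E"): 1.0,
}


@dataclass(frozen=True)
class SeverityGrade:
    """A single grade on the extended severity scale."""

    category: str
    subclass: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown severity category: {self.category!r}")
        if self.category == "extremely severe":
            if self.subclass not in SUBCLASSES:
                raise ValueError("extremely severe grade requires subclass A-E")
        elif self.subclass is not None:
            raise ValueError("subclass only valid for the extremely severe category")

    def numeric(self, scores: dict[tuple[str, str | None], float] | None = None) -> float:
        table = DEFAULT_SCORES if scores is None else scores
        return table[(self.category, self.subclass)]

    @classmethod
    def parse(cls, text: str) -> "SeverityGrade":
        """Parse labels like ``"extremely severe D"`` or the shorthand
        ``"Severe D"`` (a trailing grade letter implies the extremely
        severe category, since plain severe has no subclasses)."""
        toks = text.strip().lower().split()
        subclass = None
        if toks and toks[-1].upper() in SUBCLASSES and len(toks[-1]) == 1:
            subclass = toks[-1].upper()
            toks = toks[:-1]
        category = " ".join(toks)
        if subclass is not None and category in {"severe", "extremely severe", ""}:
            category = "extremely severe"
        return cls(category=category, subclass=subclass)

    def __str__(self) -> str:
        if self.subclass:
            return f"{self.category} {self.subclass}"
        return self.category


@dataclass
class SeverityTimeline:
    """Dated severity grades, resolvable against panel sample dates."""

    records: list[tuple[pd.Timestamp, SeverityGrade]]

    def __post_init__(self) -> None:
        self.records = [(pd.Timestamp(d).normalize(), g) for d, g in self.records]
        self.records.sort(key=lambda r: r[0])

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeverityTimeline":
        df = pd.read_csv(path)
        return cls([(pd.Timestamp(row["date"]), SeverityGrade.parse(row["severity"]))
                    for _, row in df.iterrows()])

    @classmethod
    def from_json(cls, path: str | Path) -> "SeverityTimeline":
        df = pd.read_json(path)
        return cls([(pd.Timestamp(row["date"]), SeverityGrade.parse(row["severity"]))
                    for _, row in df.iterrows()])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"date": [d.strftime("%Y-%m-%d") for d, _ in self.records],
             "severity": [str(g) for _, g in self.records]}
        ).to_csv(path, index=False)

    def resolve(self, date) -> SeverityGrade:
        """Grade recorded on the given calendar day."""
        day = pd.Timestamp(date).normalize()
        for d, g in self.records:
            if d == day:
                return g
        raise KeyError(f"no severity grade recorded for {day.date()}")


def encode_severity(
    timeline: SeverityTimeline,
    sample_dates,
    scheme: str = "ordinal",
    scores: dict[tuple[str, str | None], float] | None = None,
) -> np.ndarray:
    """Numeric health-state vector aligned to panel sample order.

    ``ordinal`` applies the numeric severity coding (higher = less
    impaired). ``binary_last`` codes every sample 0 except the final
    one, which is 1 — the two-level contrast used when the patient
    improved only at the last draw. A constant ordinal vector is
    returned as-is; downstream correlation marks it degenerate.
    """
    dates = [pd.Timestamp(d) for d in sample_dates]
    if scheme == "binary_last":
        for d in dates:
            timeline.resolve(d)  # still require resolvable grades
        out = np.zeros(len(dates))
        out[-1] = 1.0
        return out
    if scheme == "ordinal":
        return np.array([timeline.resolve(d).numeric(scores) for d in dates])
    raise ValueError(f"unknown severity coding scheme: {scheme!r}")
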