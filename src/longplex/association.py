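"""Pearson correlation of analytes and medication doses vs health state.

With a two-level health-state vector (the typical N-of-1 contrast:
a run of samples at one severity grade and a final improved one) the
Pearson coefficient is the point-biserial correlation, and its
magnitude is invariant to the numeric codes chosen for the two levels.

Medication doses are min-max scaled per medication before correlation;
since Pearson is affine-invariant this affects presentation only, and
constant-dose medications are flagged degenerate rather than correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from longplex.medications import MedicationLog
from longplex.panel import AnalytePanel


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided t-test p-value.

    p is from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    ``degenerate`` marks zero variance on either side, in which case r
    and p are None.
    """

    r: float | None
    p: float | None
    n: int
    degenerate: bool = False


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise-complete missing handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 paired non-missing observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=None, p=None, n=n, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def severity_correlations(
    panel: AnalytePanel,
    health_state,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-analyte Pearson correlation against the health-state coding.

    Returns a DataFrame indexed by analyte with columns r, p, n,
    degenerate and sig (p <= cutoff), sorted by descending r.
    """
    hs = np.asarray(health_state, dtype=float)
    if hs.size != panel.n_timepoints:
        raise ValueError("health_state length must match panel timepoints")
    rows = {}
    for analyte in panel.analyte_ids:
        x = panel.mfi[analyte].to_numpy(dtype=float)
        try:
            res = pearson(x, hs)
        except ValueError as exc:
            rows[analyte] = dict(r=np.nan, p=np.nan, n=0, degenerate=True,
                                 sig=False, note=str(exc))
            continue
        rows[analyte] = dict(
            r=np.nan if res.degenerate else res.r,
            p=np.nan if res.degenerate else res.p,
            n=res.n,
            degenerate=res.degenerate,
            sig=bool(res.p is not None and res.p <= p_cutoff),
            note="",
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "analyte"
    return df.sort_values("r", ascending=False)


def minmax_scale(doses) -> tuple[np.ndarray, bool]:
    """Min-max scale a dose series to [0, 1].

    Missing entries stay missing. A constant series scales to all zeros
    and is flagged degenerate; an all-missing series is an error.
    """
    d = np.asarray(doses, dtype=float)
    present = d[~np.isnan(d)]
    if present.size == 0:
        raise ValueError("all doses missing")
    lo, hi = present.min(), present.max()
    if hi == lo:
        out = np.where(np.isnan(d), np.nan, 0.0)
        return out, True
    return (d - lo) / (hi - lo), False


def window_dose(log: MedicationLog, sample_date, window_days: int = 3) -> pd.Series:
    """Mean recorded dose per medication within +/- window_days of the
    draw date; missing where no dose was recorded in the window."""
    return log.dose_on(sample_date, window_days=window_days)


def medication_correlations(
    log: MedicationLog,
    sample_dates,
    health_state,
    mode: str = "day_of_draw",
    window_days: int = 3,
    missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-medication scaled dose vs health state.

    ``mode`` selects the dose construction: ``day_of_draw`` uses only
    doses recorded on the draw date; ``window`` averages doses within
    +/- ``window_days``. Medications with constant or absent dose
    series are excluded with a reason. By default an unrecorded dose is
    missing and drops out pairwise; ``missing_as_zero`` treats it as a
    zero dose instead.
    """
    if mode == "day_of_draw":
        doses = log.dose_matrix(sample_dates, window_days=0)
    elif mode == "window":
        doses = log.dose_matrix(sample_dates, window_days=window_days)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    hs = np.asarray(health_state, dtype=float)
    rows = {}
    for med in doses.index:
        series = doses.loc[med].to_numpy(dtype=float)
        if missing_as_zero:
            series = np.nan_to_num(series, nan=0.0)
        if np.all(np.isnan(series)):
            rows[med] = dict(r=np.nan, p=np.nan, n=0, degenerate=True,
                             note="no recorded doses")
            continue
        scaled, degenerate = minmax_scale(series)
        if degenerate:
            rows[med] = dict(r=np.nan, p=np.nan,
                             n=int(np.sum(~np.isnan(series))), degenerate=True,
                             note="constant dose")
            continue
        try:
            res = pearson(scaled, hs)
        except ValueError as exc:
            rows[med] = dict(r=np.nan, p=np.nan, n=0, degenerate=True, note=str(exc))
            continue
        rows[med] = dict(
            r=np.nan if res.degenerate else res.r,
            p=np.nan if res.degenerate else res.p,
            n=res.n, degenerate=res.degenerate,
            note="degenerate health state" if res.degenerate else "",
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "medication"
    return df.sort_values("r", ascending=False)
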