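"""Last-vs-baseline outlier statistics for a longitudinal panel.

The core N-of-1 chain: per analyte, the final timepoint is standardized
against the mean and standard deviation of all earlier timepoints,

    z = (x_T - mean(x_1..x_{T-1})) / sd(x_1..x_{T-1}),

the z-score is converted to a two-tailed normal p-value
p = 2 * (1 - Phi(|z|)), and p-values are adjusted across the panel by
the Benjamini-Hochberg step-up procedure with the multiplicity m set to
the number of analytes measured (not the number reported).

Because the baseline SD is estimated from few points while the p-value
treats z as exactly normal, the nominal test is anti-conservative: with
8 baseline points the statistic is sqrt(9/8) * t_7 and the true
rejection rate at nominal p <= 0.05 is about 0.107. The calibration
suite quantifies this; it is a property of the method, not a bug in the
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from longplex.panel import AnalytePanel

#: selection thresholds used for the reported flag columns
Z_THRESHOLD = 1.0
P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.10


@dataclass
class OutlierTable:
    """Per-analyte outlier statistics.

    ``table`` is indexed by analyte with columns ``z``, ``p``, ``q``,
    ``direction``, ``passes_z1`` (|z| >= 1), ``passes_sig`` (|z| > 1 and
    p <= 0.05), ``passes_fdr10`` (q <= 0.10), ``baseline_n`` and
    ``note`` (exclusion reason, empty if analyzed). ``m`` is the panel
    size used for the FDR adjustment.
    """

    table: pd.DataFrame
    m: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["passes_sig"].fillna(False)]

    @property
    def fdr_selected(self) -> pd.DataFrame:
        return self.table[self.table["passes_fdr10"].fillna(False)]

    def to_csv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"z": "Z score", "p": "p-value", "q": "fdr"}
        )
        out.index.name = "Cytokine"
        out.to_csv(path)


def log2_transform(panel: AnalytePanel) -> AnalytePanel:
    """Elementwise log2 of the MFI matrix; missing cells stay missing."""
    if panel.log_scale:
        raise ValueError("panel is already on the log2 scale")
    values = panel.mfi.to_numpy(dtype=float)
    bad = np.argwhere(np.nan_to_num(values, nan=1.0) <= 0)
    if len(bad):
        cells = [
            f"({panel.sample_ids[i]}, {panel.analyte_ids[j]})" for i, j in bad[:10]
        ]
        raise ValueError(f"non-positive MFI values at cells: {', '.join(cells)}")
    mfi = panel.mfi.copy()
    mfi.loc[:, :] = np.log2(values)
    return replace(panel, mfi=mfi, log_scale=True)


def last_vs_baseline_z(values: Sequence[float], ddof: int = 1) -> float:
    """Standard score of the final observation against all earlier ones.

    The baseline mean and SD use the non-missing values among
    x_1..x_{T-1}; at least 3 are required. Returns NaN when the final
    value is missing or the baseline SD is zero (the analyte is flagged
    and excluded downstream rather than erroring the whole panel).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D series with at least 2 timepoints")
    baseline = arr[:-1]
    baseline = baseline[~np.isnan(baseline)]
    if baseline.size < 3:
        raise ValueError(f"need >= 3 non-missing baseline values, got {baseline.size}")
    last = arr[-1]
    if np.isnan(last):
        return np.nan
    sd = baseline.std(ddof=ddof)
    if sd == 0:
        return np.nan
    return float((last - baseline.mean()) / sd)


def two_tailed_p(z) -> np.ndarray | float:
    """Two-tailed normal p-value, p = 2 * (1 - Phi(|z|)).

    Floored at the smallest positive normal float so downstream FDR
    values stay strictly positive.
    """
    z = np.asarray(z, dtype=float)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    p = np.where(np.isnan(z), np.nan, p)
    return float(p) if p.ndim == 0 else p


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    With the supplied p-values treated as the ``len(p)`` smallest of
    ``m`` tests, the adjusted value for the i-th smallest is
    q_(i) = min(1, min_{j >= i} p_(j) * m / j). ``m`` defaults to
    ``len(p)`` and must not be smaller. NaN inputs yield NaN outputs and
    do not participate in ranking. Output is in the input order.
    """
    p = np.asarray(p, dtype=float)
    mask = ~np.isnan(p)
    vals = p[mask]
    k = vals.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m={m} smaller than number of p-values ({k})")
    if k and (np.any(vals <= 0) or np.any(vals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full_like(p, np.nan)
    if k:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, k + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(k)
        out[order] = np.minimum(stepped, 1.0)
        q[mask] = out
    return q


def outlier_table_from_z(
    z: Sequence[float] | pd.Series,
    names: Sequence[str] | None = None,
    m: int | None = None,
    baseline_n: int | None = None,
) -> OutlierTable:
    """Build an :class:`OutlierTable` from precomputed z-scores.

    Useful when only the standardized scores are available (e.g. a
    published results table) and the p/q chain and selection flags are
    to be reconstructed.
    """
    if isinstance(z, pd.Series):
        names = list(z.index) if names is None else list(names)
        z = z.to_numpy(dtype=float)
    else:
        z = np.asarray(z, dtype=float)
        if names is None:
            names = [f"analyte{i:03d}" for i in range(len(z))]
    if m is None:
        m = int(np.sum(~np.isnan(z)))
    p = two_tailed_p(z)
    q = bh_adjust(p, m=m)
    nan = np.isnan(z)

    def flag(values: np.ndarray) -> pd.array:
        return pd.array(np.where(nan, None, values), dtype="boolean")

    table = pd.DataFrame(
        {
            "z": z,
            "p": p,
            "q": q,
            "direction": np.sign(z),
            "passes_z1": flag(np.abs(z) >= Z_THRESHOLD),
            "passes_sig": flag((np.abs(z) > Z_THRESHOLD) & (p <= P_THRESHOLD)),
            "passes_fdr10": flag(q <= FDR_THRESHOLD),
            "baseline_n": baseline_n,
            "note": "",
        },
        index=pd.Index(names, name="analyte"),
    )
    return OutlierTable(table=table, m=m)


def run_outlier_analysis(
    panel: AnalytePanel,
    m: int | None = None,
    sd_ddof: int = 1,
) -> OutlierTable:
    """Full per-analyte chain on a QC'd, log2-transformed panel.

    Analytes whose baseline SD is zero or whose final value is missing
    are excluded from the multiple-testing adjustment and carry a note;
    ``m`` defaults to the number of analyzable analytes.
    """
    if not panel.log_scale:
        raise ValueError("panel must be log2-transformed first (log2_transform)")
    zs: list[float] = []
    notes: list[str] = []
    baseline_ns: list[int] = []
    for analyte in panel.analyte_ids:
        series = panel.mfi[analyte].to_numpy(dtype=float)
        baseline = series[:-1]
        n_base = int(np.sum(~np.isnan(baseline)))
        baseline_ns.append(n_base)
        if n_base < 3:
            zs.append(np.nan)
            notes.append("fewer than 3 baseline values")
            continue
        z = last_vs_baseline_z(series, ddof=sd_ddof)
        if np.isnan(z):
            zs.append(np.nan)
            notes.append(
                "missing final value" if np.isnan(series[-1]) else "zero baseline SD"
            )
        else:
            zs.append(z)
            notes.append("")
    result = outlier_table_from_z(np.array(zs), names=panel.analyte_ids, m=m)
    result.table["note"] = notes
    result.table["baseline_n"] = baseline_ns
    return result
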