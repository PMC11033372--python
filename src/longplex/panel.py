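"""Multiplex panel container, I/O, and bead-count quality control.

An :class:`AnalytePanel` holds a timepoint x analyte matrix of raw
median fluorescence intensity (MFI) values from a bead-based multiplex
immunoassay, with optional per-well bead counts, a panel assignment
(which multiplex kit each analyte was measured on) and per-panel
dilution factors.

Quality control follows the standard bead-count rule for Luminex-style
readouts: wells with fewer than 50 beads are flagged, and wells with
fewer than 20 beads are excluded (the MFI becomes missing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

QC_OK = "ok"
QC_FLAGGED = "flagged"
QC_EXCLUDED = "excluded"

#: bead-count thresholds: below ``BEAD_EXCLUDE`` the well is dropped,
#: below ``BEAD_FLAG`` it is flagged but retained.
BEAD_FLAG = 50
BEAD_EXCLUDE = 20


@dataclass
class AnalytePanel:
    """Timepoint x analyte MFI matrix with QC metadata.

    Parameters
    ----------
    mfi
        DataFrame indexed by sample date (DatetimeIndex, strictly
        increasing), one column per analyte. Values are raw MFI
        (strictly positive where present) unless ``log_scale`` is set,
        in which case they are log2 MFI. Missing cells are NaN.
    bead_count
        Optional DataFrame of integer bead counts, same shape as ``mfi``.
    qc_flag
        Optional DataFrame of {"ok", "flagged", "excluded"} per cell.
    panel_assignment
        Optional map analyte -> panel number.
    dilution
        Optional map panel number -> fold dilution.
    log_scale
        True once the matrix has been log2-transformed.
    """

    mfi: pd.DataFrame
    bead_count: pd.DataFrame | None = None
    qc_flag: pd.DataFrame | None = None
    panel_assignment: dict[str, int] | None = None
    dilution: dict[int, float] | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.mfi.shape[0] == 0:
            raise ValueError("no samples")
        if not isinstance(self.mfi.index, pd.DatetimeIndex):
            self.mfi = self.mfi.copy()
            self.mfi.index = pd.to_datetime(self.mfi.index)
        if self.mfi.index.has_duplicates:
            dupes = self.mfi.index[self.mfi.index.duplicated()].unique()
            raise ValueError(f"duplicate sample dates: {list(dupes.strftime('%Y-%m-%d'))}")
        if not self.mfi.index.is_monotonic_increasing:
            order = self.mfi.index.argsort()
            self.mfi = self.mfi.iloc[order]
            if self.bead_count is not None:
                self.bead_count = self.bead_count.iloc[order]
            if self.qc_flag is not None:
                self.qc_flag = self.qc_flag.iloc[order]
        for name, other in (("bead_count", self.bead_count), ("qc_flag", self.qc_flag)):
            if other is not None and other.shape != self.mfi.shape:
                raise ValueError(f"{name} shape {other.shape} != mfi shape {self.mfi.shape}")
        if self.panel_assignment is not None:
            missing = [a for a in self.mfi.columns if a not in self.panel_assignment]
            if missing:
                raise ValueError(f"analytes missing from panel map: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mfi.index.strftime("%Y-%m-%d"))

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.mfi.columns)

    @property
    def n_timepoints(self) -> int:
        return self.mfi.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.mfi.shape[1]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_panel(
    path: str | Path,
    bead_counts: str | Path | None = None,
    panel_map: str | Path | Mapping | None = None,
) -> AnalytePanel:
    """Read a delimited MFI table into an :class:`AnalytePanel`.

    The table must have one row per sample with a parseable date in the
    first column (named ``date``) and one column per analyte.
    Non-numeric cells become missing. Samples are returned sorted by
    date; duplicate dates are an error.
    """
    raw = _read_table(path)
    if raw.shape[0] == 0:
        raise ValueError("no samples")
    raw = raw.set_index(raw.columns[0])
    raw.index = pd.to_datetime(raw.index)
    mfi = raw.apply(pd.to_numeric, errors="coerce")

    bead_df = None
    if bead_counts is not None:
        braw = _read_table(bead_counts)
        braw = braw.set_index(braw.columns[0])
        braw.index = pd.to_datetime(braw.index)
        bead_df = braw.apply(pd.to_numeric, errors="coerce")
        bead_df = bead_df.reindex(index=mfi.index, columns=mfi.columns)

    assignment = dilution = None
    if panel_map is not None:
        assignment, dilution = load_panel_map(panel_map)

    return AnalytePanel(
        mfi=mfi,
        bead_count=bead_df,
        panel_assignment=assignment,
        dilution=dilution,
    )


def load_panel_map(source: str | Path | Mapping) -> tuple[dict[str, int], dict[int, float]]:
    """Read a YAML panel map: panel number -> {dilution, analytes}."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    assignment: dict[str, int] = {}
    dilution: dict[int, float] = {}
    for panel_id, entry in doc.items():
        pid = int(panel_id)
        dilution[pid] = float(entry["dilution"])
        for analyte in entry["analytes"]:
            assignment[str(analyte)] = pid
    return assignment, dilution


def write_panel(panel: AnalytePanel, path: str | Path, bead_path: str | Path | None = None) -> None:
    """Write the MFI matrix (and optionally bead counts) back to CSV.

    Uses full float repr so a load/write round trip reproduces every
    non-missing value bit-exactly.
    """
    out = panel.mfi.copy()
    out.insert(0, "date", panel.mfi.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.17g")
    if bead_path is not None and panel.bead_count is not None:
        bout = panel.bead_count.copy()
        bout.insert(0, "date", panel.bead_count.index.strftime("%Y-%m-%d"))
        bout.to_csv(bead_path, index=False)


def apply_bead_qc(panel: AnalytePanel) -> AnalytePanel:
    """Apply the bead-count QC rule and return a new panel.

    Cells with bead count < 20 are excluded (MFI set to missing);
    counts in [20, 50) are flagged but the value is retained; counts
    >= 50 pass. Requires a bead-count matrix.
    """
    if panel.bead_count is None:
        raise ValueError("bead_count matrix required for QC")
    counts = panel.bead_count.to_numpy(dtype=float)
    if np.nanmin(counts) < 0:
        raise ValueError("negative bead counts")

    flags = np.full(counts.shape, QC_OK, dtype=object)
    flags[counts < BEAD_FLAG] = QC_FLAGGED
    flags[counts < BEAD_EXCLUDE] = QC_EXCLUDED
    # wells with no recorded count pass through untouched
    flags[np.isnan(counts)] = QC_OK

    mfi = panel.mfi.copy()
    mfi_values = mfi.to_numpy(dtype=float)
    mfi_values[flags == QC_EXCLUDED] = np.nan
    mfi.loc[:, :] = mfi_values

    qc = pd.DataFrame(flags, index=panel.mfi.index, columns=panel.mfi.columns)
    return replace(panel, mfi=mfi, qc_flag=qc)
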