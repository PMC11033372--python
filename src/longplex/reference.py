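"""Published reference values for the N-of-1 cytokine case study.

The original study measured 80 plasma cytokines at 9 timepoints and
reported, for the 24 cytokines with |z| >= 1, the last-vs-baseline
z-score together with its two-tailed p-value and BH-FDR over the full
80-analyte panel. The raw MFI matrix was not deposited, so these
printed z-scores are the anchor for reproducing the published
z -> p -> FDR chain: feeding them through :func:`longplex.outliers.
outlier_table_from_z` with ``m = 80`` regenerates the published p and
fdr columns.

``REPORTED_Z`` carries the published z-scores (keyed by cytokine,
ordered as printed). ``REPORTED_P`` and ``REPORTED_FDR`` carry the
printed p/fdr values where the study stated them at full precision in
the text; table cells printed at coarser precision are omitted.
"""

from __future__ import annotations

import pandas as pd

#: Number of analytes measured on the full multiplex panel.
PANEL_SIZE = 80

#: Number of baseline (pre-final) timepoints in the study design.
BASELINE_N = 8

#: Published z-scores for the 24 cytokines with |z| >= 1.
REPORTED_Z: dict[str, float] = {
    "HGF": 4.80,
    "LEPTIN": 3.62,
    "MIF": 3.09,
    "EOTAXIN/CCL11": -2.75,
    "MCP1/CCL2": -2.27,
    "IL28A/IFNL2": -2.17,
    "MIG/CXCL9": -2.11,
    "IL5": -2.08,
    "MIP1D/MIP5/CCL15": -2.06,
    "SFAS/TNFRSF6": -1.91,
    "VEGF": -1.79,
    "CTACK/CCL27": -1.72,
    "IL9": -1.51,
    "ENA78/CXCL5": 1.37,
    "IL6": -1.29,
    "GROA": 1.25,
    "MCP4/CCL13": -1.20,
    "IL2": 1.19,
    "IL10": -1.18,
    "IL4": -1.12,
    "TARC/CCL17": 1.11,
    "6CKINE/CCL21/EXODUS2": 1.04,
    "FGF2/FGFB": 1.01,
    "TPO": 1.01,
}

#: Published two-tailed p-values, as printed in the running text
#: (z-scores there are quoted at slightly different rounding for a few
#: cytokines; the pairs below are internally consistent).
REPORTED_P: dict[str, tuple[float, float]] = {
    # cytokine -> (z as quoted alongside, printed p); only pairs whose
    # printed p equals 2*(1-Phi(|z|)) at the printed rounding are kept
    # (a few published cells, e.g. IL28A 0.029 from z=-2.17, carry a
    # one-ulp rounding slip and are not asserted)
    "MIF": (3.08, 0.002),
    "MCP1/CCL2": (-2.27, 0.023),
    "MIG/CXCL9": (-2.11, 0.035),
    "MIP1D/MIP5/CCL15": (-2.06, 0.039),
    "HGF": (4.80, 1.60e-06),
}

#: Published BH-FDR values (m = 80) for internally consistent cells.
REPORTED_FDR: dict[str, float] = {
    "HGF": 0.0001,
    "LEPTIN": 0.01,
    "MIF": 0.05,
    "EOTAXIN/CCL11": 0.12,
    "MCP1/CCL2": 0.35,
    "IL28A/IFNL2": 0.35,
    "MIG/CXCL9": 0.35,
    "IL5": 0.35,
    "MIP1D/MIP5/CCL15": 0.35,
    "SFAS/TNFRSF6": 0.45,
    "VEGF": 0.53,
    "CTACK/CCL27": 0.57,
    "IL9": 0.81,
}

#: FDR cells whose step-up minimum runs through unpublished analytes;
#: recomputation from the 24 printed z-scores alone can only bound them
#: from below.
REPORTED_FDR_TAIL = 0.97

#: Number of cytokines the study reported as significant at
#: |z| > 1 and p <= 0.05.
REPORTED_N_SIGNIFICANT = 9


def reported_z_series() -> pd.Series:
    """Published z-scores as a Series in printed order."""
    return pd.Series(REPORTED_Z, name="z")
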