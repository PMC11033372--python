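# longplex

Analysis toolkit for **N-of-1 longitudinal multiplex cytokine studies**:
a single patient, a handful of blood draws over several years, ~80
plasma cytokines measured by a bead-based multiplex immunoassay
(Luminex-style median fluorescence intensity, MFI), and the contextual
records such a study keeps — a disease-severity timeline, a
medication/supplement dose log, and a dated corpus of patient-authored
blog posts.

The motivating setting is extremely severe ME/CFS, where patients are
bedbound and conventional cohort designs are infeasible; the question
is which analytes move when a single patient's health state changes.

## The statistical core

For each analyte, with log2-MFI values x_1 … x_T over T timepoints, the
final sample is standardized against all earlier ones:

    z = (x_T − mean(x_1..x_{T−1})) / sd(x_1..x_{T−1})        (sd: ddof=1)
    p = 2 · (1 − Φ(|z|))                                      (two-tailed normal)
    q = BH step-up over the panel with multiplicity m = panel size

Selection uses |z| > 1 with p ≤ 0.05, and q ≤ 0.10 for the
FDR-controlled set. Around this chain the package provides:

- **Bead-count QC** — wells with < 50 beads flagged, < 20 excluded.
- **Severity scale** — the extended 1–10 scale with "extremely severe"
  grades A–E (A least impaired), plus ordinal and last-sample-binary
  health-state codings.
- **Correlation** — Pearson r (point-biserial for two-level health
  states) of analytes and min-max-scaled medication doses against the
  health state, with day-of-draw or ±3-day dose windows.
- **Clustering** — agglomerative Ward.D2 on unsquared Euclidean
  distances (Lance–Williams update), leaf orders and heatmap exports.
- **Text trends** — monthly/yearly activity and post length, ranked
  word frequencies, Fisher exact comparison of sentiment distributions
  between periods, and a from-scratch collapsed-Gibbs LDA topic model.
- **Synthetic data** — seeded generators for every input (panel with
  designated "responder" analytes shifted at the final timepoint,
  severity timeline, dose log, post stream), so the full pipeline is
  testable offline.

## Worked example

```python
>>> from longplex import reference
>>> from longplex.outliers import outlier_table_from_z
>>> table = outlier_table_from_z(reference.reported_z_series(), m=80)
>>> table.table.loc["HGF", "q"].round(4)
0.0001
>>> len(table.significant)      # |z| > 1 and p <= 0.05
9
>>> list(table.fdr_selected.index)   # q <= 0.10
['HGF', 'LEPTIN', 'MIF']
```

`reference` bundles the 24 published last-vs-baseline z-scores from the
case study this package models (9 draws, 80 cytokines; raw MFI not
publicly deposited). Feeding them through the p → BH chain with m = 80
reproduces the published table: HGF's FDR value 0.0001, nine analytes
significant before adjustment, and exactly HGF, Leptin and MIF
surviving FDR ≤ 10%.

The synthetic route exercises the same chain end to end:

```bash
longplex simulate --out-dir demo --seed 7
longplex analyze-panel demo/panel.csv --bead-counts demo/bead_counts.csv --out demo/table.csv
```

which prints `13 analytes significant (|z| > 1, p <= 0.05); m = 80` for
that seed — the three planted responders plus the false positives the
anti-conservative normal p-value admits before FDR control (see
`docs/methods.md`; the nominal p ≤ 0.05 rule rejects ≈ 10.7% of null
analytes, so ~8–9 of the 13 are expected noise). A YAML config naming
the generated files drives the full pipeline via `longplex run-all
--config config.yaml`, writing all tables plus a `report.md` that
restates every setting in force.

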