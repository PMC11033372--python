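# Methods

## The measurement model

A bead-based multiplex immunoassay reports, per well, a median
fluorescence intensity (MFI) per analyte together with a bead count.
MFI spans orders of magnitude across analytes and is right-skewed, so
all analysis is done on log2 MFI. Bead-count QC follows the standard
reliability rule for this platform: wells with fewer than 50 beads are
flagged (value retained), fewer than 20 are excluded (value becomes
missing). Missing cells are excluded pairwise from every downstream
statistic; nothing is imputed.

Analytes are assayed on up to three kit panels with per-panel fold
dilutions (3, 3, 10 by default). Dilution metadata is carried, not
corrected for: the outlier statistic is invariant to any per-analyte
positive scale factor, because z-scores on the log2 scale are invariant
to additive offsets.

## Last-vs-baseline outlier statistic

For each analyte with values x_1 … x_T over T timepoints (T = 9 in the
motivating design), the final sample is compared with the baseline of
all earlier samples:

    z = (x_T − mean(x_1..x_{T−1})) / sd(x_1..x_{T−1}).

The baseline SD uses **ddof = 1** (sample SD). The convention is not
recoverable from the published table without the raw matrix, so it is
configurable (`sd_ddof`); the published p/fdr reproduction is
independent of this choice because it starts from the printed z-scores.
At least 3 non-missing baseline values are required; a zero baseline SD
excludes the analyte with a recorded reason rather than failing the
run.

P-values are **two-tailed normal**: p = 2(1 − Φ(|z|)), floored at the
smallest positive float so adjusted values stay positive. This is the
method's deliberate simplification, and it is *anti-conservative*:
under normal noise with n baseline points, z is distributed as
√(1 + 1/n) · t_{n−1}, not N(0,1). With n = 8 the true rejection rate at
nominal p ≤ 0.05 is

    2 · P(t₇ > 1.96 / √(9/8)) ≈ 0.107,

and the inflation grows in the far tail (at nominal p = 0.005 the true
tail mass is ≈ 0.033, a factor ~6.6). The calibration suite measures
this on the null generator and the acceptance script reports it
(`null_rejection_fraction`). Consequence: at FDR ≤ 0.10 over 80
analytes with 3 strong true signals, the selection admits ≈ 3 null
analytes on average — the nominal 10% FDR is not achieved. The package
reports this honestly (`mean_false_positives`); users who need
calibrated error control at these sample sizes should treat the
selection as a ranked shortlist, not an inferential guarantee.

Multiple testing uses the **Benjamini–Hochberg step-up**,
q_(i) = min(1, min_{j≥i} p_(j)·m/j), implemented in-package and
cross-checked against statsmodels. The multiplicity **m defaults to
every analyte measured**, not the subset reported: over a published
24-row excerpt of an 80-plex panel, only m = 80 reproduces the
published smallest FDR cell (1.6e-6 · 80 / 1 = 1.28e-4 → 0.0001 at the
printed precision). When only the k smallest p-values of m tests are
supplied, they are ranked 1..k on the assumption they are the smallest
of m; adjusted values whose step-up minimum would run through the
unsupplied tests are therefore lower bounds, and the tests assert them
as such.

### The bundled reference table

`longplex.reference` carries the 24 published z-scores of the case
study (the raw MFI matrix was never deposited). Published p-value cells
that are inconsistent with their own z at the printed rounding (e.g.
0.029 printed for z = −2.17, which recomputes to 0.0300) are recorded
but not asserted; the printed table also duplicates its first row,
which is dropped. All reproduction starts from the z column, the only
internally consistent anchor.

## Severity scale and health-state coding

The extended severity framework is a 1–10 scale over five categories,
with "extremely severe" subdivided A–E; **A is the least impaired
subclass** (a patient improving moves D → A). The literature defines
the ordering but no numeric values, so the default coding (mild 9,
moderate 7, severe 5, very severe 3, extremely severe A–E =
2.0/1.75/1.5/1.25/1.0) is one admissible monotone choice, exposed as a
parameter. Two codings are provided for correlation: `ordinal` (the
mapping above) and `binary_last` (0 for all draws, 1 for the final
one). With only two observed grades — the motivating design: eight
draws at extremely severe D, one at A — Pearson correlation is
point-biserial and |r| is provably identical under every monotone
two-value coding, so the ambiguity is presentational; reports always
state the coding used.

## Correlations

Pearson r with pairwise-complete observations and the two-sided t test
p-value on n−2 df (scipy's estimator, property-tested against the
from-definition sums). Degenerate inputs (constant on either side) are
flagged, never silently zero. Medication doses are aligned to draw
dates either as the dose recorded on the day of draw or as the mean
over a ±3-day window, min-max scaled per medication before correlation
(presentation only — Pearson is affine-invariant); constant-dose
medications are reported as degenerate and absent medications as
unobserved. Unrecorded doses are missing by default; a
`missing_as_zero` option treats them as zero dose, since real-world
dose logs are ambiguous about omission vs discontinuation.

## Clustering

Agglomerative clustering with Euclidean distance and **Ward.D2**
linkage: squared distances inside the Lance–Williams update,

    d(k, i∪j)² = [(nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖd²ᵢⱼ] / (nᵢ+nⱼ+nₖ),

heights reported unsquared. Implementation is a greedy global-minimum
O(n³) agglomeration — panels have tens of rows, so clarity wins over
the nn-chain algorithm — with a deterministic tie-break (lowest cluster
id pair) for platform-stable output. It is verified against scipy's
Ward linkage and, on small instances, against an independent oracle
that computes each merge cost directly from cluster centroids. Leaf
order is plain recursive subtree order without optimal-leaf reordering.
Rows with missing values are dropped from clustering with a log line,
not imputed. Sample-axis clustering defaults to raw log2 values;
per-row z-scoring is available for display.

## Text analytics

Tokenization is Unicode word characters, lowercased, possessive 's
stripped; the default stopword list is the package's own small English
list and fully configurable. Activity series zero-fill quiet periods so
multi-year gaps are visible. Sentiment labels are an input: any
external labeler (human, lexicon, transformer) may attach
negative/neutral/positive labels; the package only aggregates them.
Period-to-period sentiment shifts use Fisher's exact test on 2×2 tables
(two chosen sentiment classes × two periods, third class excluded),
with the probability-mass two-sided rule and the sample cross-product
odds ratio (conditional MLE behind a flag). The contingency row order
follows the later-period-first convention so "negative vs positive OR
< 1" reads as *negative sentiment declined*.

Topic modeling is **latent Dirichlet allocation fit by collapsed Gibbs
sampling**, written in-package: symmetric priors α = 50/K, β = 0.01,
single chain, seeded and fully deterministic; φ and θ are posterior
means from the final-iteration counts. Default 1000 iterations;
the test corpora use 100–200, which suffices for the small vocabularies
there. The log joint likelihood is tracked every 10 iterations for
burn-in monitoring (asserted to improve over the run, not per
iteration, since Gibbs chains are not monotone).

## Synthetic data generator

The generator emulates the study conditions: 9 timepoints, 80 analytes,
per-analyte log2 baselines uniform on [6, 14], within-analyte noise
normal on the log2 scale with σ = 0.5, a configurable responder set
shifted by δ·σ at the final timepoint only (δ = 4 in the recovery
experiments), bead counts Poisson(1000) with an optional low-count
contamination rate, a severity timeline of eight extremely-severe-D
draws and a final A, linear taper/escalation dose series (24 → 7 mg
default taper), and monthly Poisson post streams with per-year
sentiment mixes and per-topic vocabularies (the true topic is recorded
for recovery scoring). A heavy-tailed noise option (t₃, rescaled)
exists but is off by default.

What the generator does **not** emulate: inter-panel batch effects,
plate layouts, standard curves, assay drift, autocorrelated
within-patient trends, or realistic language. Passing tests therefore
demonstrate the statistical chain's correctness and its behaviour under
idealized noise, not robustness to real assay artifacts.

## Problem sizes and numerical choices

The calibration experiment uses 20,000 simulated null analytes (Monte
Carlo SE ≈ 0.002 on a fraction of 0.107); recovery and sign-agreement
experiments use 200 seeded replicates of the full 9×80 design. BH and
Fisher implementations are exact (no asymptotics); p-value ties in BH
are ranked stably by input order, which the step-up minimum makes
order-independent anyway. All generator and sampler randomness flows
from `numpy.random.default_rng(seed)`; identical config and seed give
byte-identical outputs.

## Known limitations

- N-of-1 inference: nothing here generalizes beyond the patient
  measured; the statistics describe within-patient change.
- The normal-theory p-value is anti-conservative at these baseline
  sizes (quantified above); FDR control is nominal, not actual.
- The last-vs-baseline contrast confounds time with health state when
  only the final draw differs; the severity correlation is the same
  contrast in different clothing, and agreement between the two is
  expected, not corroborating.
- Medication correlations are descriptive associations over 9 paired
  observations with no lagging, interaction or causal adjustment.
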