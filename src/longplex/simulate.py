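"""Seeded generators for every input the pipeline consumes.

The generators emulate the data structures of a single-patient
longitudinal multiplex study: 9 roughly regular blood draws over
several years, 80 analytes with log-normal MFI baselines and normal
noise on the log2 scale, a designated set of "responder" analytes
shifted only at the final timepoint, a severity timeline that improves
only at the last draw, tapering/escalating medication dose series, and
a monthly stream of posts whose sentiment mix differs between years.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from longplex.corpus import PostCorpus
from longplex.medications import MedicationLog
from longplex.panel import AnalytePanel
from longplex.severity import SeverityGrade, SeverityTimeline


def default_sample_dates(n: int, start: str = "2017-06-29", step_days: int = 150) -> pd.DatetimeIndex:
    """Evenly spaced draw dates spanning a multi-year follow-up."""
    start_ts = pd.Timestamp(start)
    return pd.DatetimeIndex([start_ts + pd.Timedelta(days=step_days * i) for i in range(n)])


@dataclass
class PanelSimConfig:
    """Configuration of the synthetic multiplex panel.

    ``shift`` is a signed offset in units of ``noise_sd`` added to
    responder analytes at the final timepoint only; log2 baselines are
    drawn uniformly on ``baseline_log2_range``; within-analyte noise is
    normal on the log2 scale with SD ``noise_sd``. Bead counts are
    Poisson with mean ``bead_mean``; a fraction ``low_bead_rate`` of
    wells is replaced by a uniform low count in [0, 50) to exercise QC.
    ``heavy_tailed`` switches the noise to Student t with 3 df
    (rescaled to SD ``noise_sd``) for robustness experiments.
    """

    n_timepoints: int = 9
    n_analytes: int = 80
    baseline_log2_range: tuple[float, float] = (6.0, 14.0)
    noise_sd: float = 0.5
    responders: tuple[int, ...] = ()
    shift: float = 0.0
    seed: int = 0
    bead_mean: float = 1000.0
    low_bead_rate: float = 0.0
    heavy_tailed: bool = False

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("need n_timepoints >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(r < 0 or r >= self.n_analytes for r in self.responders):
            raise ValueError("responder indices out of range")


def generate_panel(config: PanelSimConfig) -> AnalytePanel:
    """Simulate a raw-MFI panel: 2^(baseline + noise), responders
    shifted by shift * noise_sd at the final timepoint."""
    if config.shift != 0 and not config.responders:
        warnings.warn("nonzero shift with empty responder set has no effect")
    rng = np.random.default_rng(config.seed)
    t, a = config.n_timepoints, config.n_analytes
    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=a)
    if config.heavy_tailed:
        noise = rng.standard_t(3, size=(t, a)) * config.noise_sd / np.sqrt(3.0)
    else:
        noise = rng.normal(0.0, config.noise_sd, size=(t, a))
    log2_mfi = baseline[None, :] + noise
    if config.responders:
        idx = list(config.responders)
        log2_mfi[-1, idx] += config.shift * config.noise_sd
    dates = default_sample_dates(t)
    analytes = [f"CYT{i:03d}" for i in range(a)]
    mfi = pd.DataFrame(2.0 ** log2_mfi, index=dates, columns=analytes)

    beads = rng.poisson(config.bead_mean, size=(t, a)).astype(float)
    if config.low_bead_rate > 0:
        low = rng.random((t, a)) < config.low_bead_rate
        beads[low] = rng.integers(0, 50, size=int(low.sum()))
    bead_count = pd.DataFrame(beads, index=dates, columns=analytes)
    assignment = {name: (i % 3) + 1 for i, name in enumerate(analytes)}
    return AnalytePanel(mfi=mfi, bead_count=bead_count,
                        panel_assignment=assignment,
                        dilution={1: 3.0, 2: 3.0, 3: 10.0})


def generate_timeline(
    n_timepoints: int,
    improved_last: bool = True,
    dates: pd.DatetimeIndex | None = None,
) -> SeverityTimeline:
    """Severity timeline: all draws at extremely severe D, with the
    final draw at extremely severe A when ``improved_last``."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if dates is None:
        dates = default_sample_dates(n_timepoints)
    grades = [SeverityGrade("extremely severe", "D")] * n_timepoints
    if improved_last:
        grades[-1] = SeverityGrade("extremely severe", "A")
    return SeverityTimeline(records=list(zip(dates, grades)))


def generate_medlog(
    patterns: dict[str, str],
    dates,
    high: float = 24.0,
    low: float = 7.0,
    supplements: tuple[str, ...] = (),
) -> MedicationLog:
    """Dose series per medication over the draw dates.

    Patterns: ``taper`` (linear high -> low), ``escalate`` (linear
    low -> high), ``constant`` (high throughout), ``absent`` (no doses
    recorded; the medication still appears in the log's roster so its
    all-missing row shows up, and is excluded from, downstream views).
    """
    dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    if len(dates) == 0:
        raise ValueError("dates must be nonempty")
    rows = []
    names = []
    for name, pattern in patterns.items():
        names.append(name)
        if pattern == "absent":
            continue
        if pattern == "taper":
            doses = np.linspace(high, low, len(dates))
        elif pattern == "escalate":
            doses = np.linspace(low, high, len(dates))
        elif pattern == "constant":
            doses = np.full(len(dates), high)
        else:
            raise ValueError(f"unknown pattern: {pattern!r}")
        for d, dose in zip(dates, doses):
            rows.append({"date": d, "name": name, "dose": float(dose),
                         "unit": "mg", "is_supplement": name in supplements})
    entries = pd.DataFrame(rows, columns=["date", "name", "dose", "unit", "is_supplement"])
    return MedicationLog(entries=entries, medications=sorted(names))


@dataclass
class CorpusSimConfig:
    """Configuration of the synthetic post stream.

    ``months`` maps "YYYY-MM" to the Poisson mean post count; the
    sentiment of each post is multinomial with the probability triple
    (negative, neutral, positive) of its year; post text is drawn from
    one of the ``topics`` vocabularies with Poisson(mean_words) length.
    Posts earlier than ``assisted_until`` are flagged as
    assisted-authorship.
    """

    months: list[tuple[str, float]] = field(default_factory=list)
    sentiment_mix: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    topics: list[list[str]] = field(default_factory=lambda: [[
        "health", "fatigue", "energy", "rest", "symptoms", "recovery",
        "doctor", "treatment", "hope", "day",
    ]])
    mean_words: float = 40.0
    assisted_until: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for year, mix in self.sentiment_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"sentiment mix for {year} does not sum to 1")
        if any(lam < 0 for _, lam in self.months):
            raise ValueError("post-count rates must be >= 0")


def generate_corpus(config: CorpusSimConfig) -> PostCorpus:
    """Simulate a dated, sentiment-labeled post stream.

    The true topic of each post is recorded in a ``topic`` column so
    topic-model recovery can be scored against the generator.
    """
    rng = np.random.default_rng(config.seed)
    sentiments = np.array(["negative", "neutral", "positive"])
    cutoff = pd.Timestamp(config.assisted_until, tz="UTC") if config.assisted_until else None
    rows = []
    for month, lam in config.months:
        period = pd.Period(month, freq="M")
        n_posts = int(rng.poisson(lam))
        for _ in range(n_posts):
            day = int(rng.integers(1, period.days_in_month + 1))
            hour = int(rng.integers(0, 24))
            ts = pd.Timestamp(year=period.year, month=period.month, day=day,
                              hour=hour, tz="UTC")
            topic = int(rng.integers(0, len(config.topics)))
            n_words = max(1, int(rng.poisson(config.mean_words)))
            words = rng.choice(config.topics[topic], size=n_words)
            mix = config.sentiment_mix.get(period.year, (1 / 3, 1 / 3, 1 / 3))
            sentiment = str(rng.choice(sentiments, p=mix))
            rows.append({
                "timestamp": ts.isoformat(),
                "text": " ".join(words),
                "sentiment": sentiment,
                "assisted": bool(cutoff is not None and ts < cutoff),
                "topic": topic,
            })
    df = pd.DataFrame(rows, columns=["timestamp", "text", "sentiment", "assisted", "topic"])
    if df.empty:
        df = pd.DataFrame({"timestamp": pd.Series(dtype=str),
                           "text": pd.Series(dtype=str),
                           "sentiment": pd.Series(dtype=object),
                           "assisted": pd.Series(dtype=bool),
                           "topic": pd.Series(dtype=int)})
    return PostCorpus(posts=df)
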