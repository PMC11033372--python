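import numpy as np
import pandas as pd
import pytest

from longplex.panel import AnalytePanel
from longplex.simulate import (
    CorpusSimConfig,
    PanelSimConfig,
    default_sample_dates,
    generate_corpus,
    generate_medlog,
    generate_panel,
    generate_timeline,
)


@pytest.fixture
def small_panel() -> AnalytePanel:
    """3 analytes x 9 timepoints with known values."""
    dates = default_sample_dates(9)
    rng = np.random.default_rng(7)
    mfi = pd.DataFrame(
        2.0 ** rng.uniform(6, 14, size=(9, 3)),
        index=dates,
        columns=["CYT000", "CYT001", "CYT002"],
    )
    beads = pd.DataFrame(
        rng.poisson(1000, size=(9, 3)).astype(float), index=dates, columns=mfi.columns
    )
    return AnalytePanel(mfi=mfi, bead_count=beads)


@pytest.fixture
def null_panel() -> AnalytePanel:
    return generate_panel(PanelSimConfig(seed=11))


@pytest.fixture
def responder_panel() -> AnalytePanel:
    return generate_panel(
        PanelSimConfig(responders=(0, 1, 2), shift=4.0, seed=11)
    )


@pytest.fixture
def study_timeline():
    return generate_timeline(9, improved_last=True)


@pytest.fixture
def taper_medlog():
    return generate_medlog(
        {"klonopin": "taper", "abilify": "escalate", "cortef": "constant",
         "ginger": "absent"},
        dates=default_sample_dates(9),
        supplements=("ginger",),
    )


@pytest.fixture
def two_topic_corpus():
    months = [(str(p), 8.0) for p in pd.period_range("2020-01", "2021-01", freq="M")]
    cfg = CorpusSimConfig(
        months=months,
        sentiment_mix={2020: (0.5, 0.3, 0.2), 2021: (0.1, 0.3, 0.6)},
        topics=[
            ["fatigue", "crash", "rest", "symptoms", "pain", "bedbound"],
            ["research", "funding", "study", "science", "review", "grant"],
        ],
        mean_words=30.0,
        assisted_until="2020-03-01",
        seed=5,
    )
    return generate_corpus(cfg)
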