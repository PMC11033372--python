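"""Text analytics: activity, word frequencies, Fisher tests, LDA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from longplex.corpus import PostCorpus
from longplex.simulate import CorpusSimConfig, generate_corpus
from longplex.textstats import (
    SentimentContingency,
    activity_series,
    fisher_exact,
    lda_fit,
    sentiment_contingency,
    tokenize,
    word_frequencies,
)


def make_corpus(rows):
    return PostCorpus(pd.DataFrame(rows))


class TestActivitySeries:
    def test_counts_and_mean_words(self):
        corpus = make_corpus([
            {"timestamp": "2020-03-05T10:00:00+00:00", "text": " ".join(["w"] * 10)},
            {"timestamp": "2020-03-15T10:00:00+00:00", "text": " ".join(["w"] * 20)},
            {"timestamp": "2020-03-25T10:00:00+00:00", "text": " ".join(["w"] * 30)},
        ])
        out = activity_series(corpus, period="month")
        assert len(out) == 1
        assert out.loc[0, "n_posts"] == 3
        assert out.loc[0, "mean_words"] == pytest.approx(20.0)

    def test_zero_fill_over_quiet_range(self):
        corpus = make_corpus([
            {"timestamp": "2020-01-05T00:00:00+00:00", "text": "hello world"},
        ])
        out = activity_series(corpus, period="month",
                              date_range=("2017-06", "2020-01"))
        assert len(out) == 32
        assert (out["n_posts"].iloc[:-1] == 0).all()
        assert out["n_posts"].iloc[-1] == 1

    def test_counts_sum_to_corpus_size(self, two_topic_corpus):
        out = activity_series(two_topic_corpus, period="month")
        assert out["n_posts"].sum() == len(two_topic_corpus)

    def test_empty_corpus(self):
        corpus = make_corpus(pd.DataFrame({"timestamp": pd.Series(dtype=str),
                                           "text": pd.Series(dtype=str)}))
        out = activity_series(corpus, period="year", date_range=("2019", "2020"))
        assert (out["n_posts"] == 0).all() and len(out) == 2


class TestWordFrequencies:
    def test_tokenizer_lowercases_and_strips_possessive(self):
        assert tokenize("The patient's CFS -- CFS!") == ["the", "patient", "cfs", "cfs"]

    def test_counts_and_tie_break(self):
        corpus = make_corpus([{"timestamp": "2020-01-01T00:00:00+00:00",
                               "text": "CFS CFS dream zebra apple zebra"}])
        out = word_frequencies(corpus, stopwords=())
        assert list(out["term"]) == ["cfs", "zebra", "apple", "dream"]
        assert list(out["count"]) == [2, 2, 1, 1]

    def test_stopwords_remove_everything(self):
        corpus = make_corpus([{"timestamp": "2020-01-01T00:00:00+00:00",
                               "text": "the and of"}])
        out = word_frequencies(corpus)
        assert out.empty

    def test_counts_sum_to_retained_tokens(self, two_topic_corpus):
        out = word_frequencies(two_topic_corpus, stopwords=())
        assert out["count"].sum() == two_topic_corpus.posts["word_count"].sum()

    def test_recovers_known_frequency_table(self):
        words = ["alpha"] * 5 + ["beta"] * 3 + ["gamma"] * 2
        corpus = make_corpus([{"timestamp": "2020-01-01T00:00:00+00:00",
                               "text": " ".join(words)}])
        out = word_frequencies(corpus, stopwords=())
        assert dict(zip(out["term"], out["count"])) == {"alpha": 5, "beta": 3, "gamma": 2}


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with the
    observed margins, probability-mass rule."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestFisherExact:
    def test_balanced_table(self):
        or_, p = fisher_exact([[5, 5], [5, 5]])
        assert or_ == 1.0 and p == 1.0

    def test_enumerated_example(self):
        or_, p = fisher_exact([[1, 9], [11, 3]])
        assert p == pytest.approx(0.0027594561852, rel=1e-9)
        assert or_ == pytest.approx((1 * 3) / (9 * 11))

    def test_extreme_table(self):
        _, p = fisher_exact([[0, 10], [10, 0]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_zero_margin(self):
        or_, p = fisher_exact([[0, 5], [0, 7]])
        assert p == 1.0 and math.isnan(or_)

    def test_symmetries(self):
        t = np.array([[3, 7], [8, 2]])
        or1, p1 = fisher_exact(t)
        or2, p2 = fisher_exact(t[::-1, ::-1])  # swap rows and columns
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert or1 == pytest.approx(or2, rel=1e-12)
        or3, _ = fisher_exact(t[::-1, :])  # single row swap inverts OR
        assert or3 == pytest.approx(1 / or1, rel=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_enumeration_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 11, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-8)


class TestSentimentContingency:
    def test_constructed_counts(self):
        rows = (
            [{"timestamp": f"2020-01-{i+1:02d}T00:00:00+00:00", "text": "x",
              "sentiment": "negative"} for i in range(10)]
            + [{"timestamp": f"2020-02-{i+1:02d}T00:00:00+00:00", "text": "x",
                "sentiment": "positive"} for i in range(10)]
            + [{"timestamp": f"2021-01-{i+1:02d}T00:00:00+00:00", "text": "x",
                "sentiment": "negative"} for i in range(2)]
            + [{"timestamp": f"2021-02-{i+1:02d}T00:00:00+00:00", "text": "x",
                "sentiment": "positive"} for i in range(15)]
            + [{"timestamp": "2021-03-01T00:00:00+00:00", "text": "x",
                "sentiment": "neutral"}]  # third category excluded
        )
        tab = sentiment_contingency(make_corpus(rows), "2020", "2021")
        np.testing.assert_array_equal(tab.as_array(), [[10, 10], [2, 15]])

    def test_post_order_irrelevant(self):
        rows = [
            {"timestamp": "2020-06-01T00:00:00+00:00", "text": "x", "sentiment": "negative"},
            {"timestamp": "2021-06-01T00:00:00+00:00", "text": "x", "sentiment": "positive"},
            {"timestamp": "2020-07-01T00:00:00+00:00", "text": "x", "sentiment": "positive"},
        ]
        t1 = sentiment_contingency(make_corpus(rows), "2020", "2021")
        t2 = sentiment_contingency(make_corpus(rows[::-1]), "2020", "2021")
        assert t1 == t2

    def test_all_one_category_zero_margin(self):
        rows = [
            {"timestamp": "2020-06-01T00:00:00+00:00", "text": "x", "sentiment": "positive"},
            {"timestamp": "2021-06-01T00:00:00+00:00", "text": "x", "sentiment": "positive"},
        ]
        tab = sentiment_contingency(make_corpus(rows), "2020", "2021")
        assert tab.zero_margin
        or_, p = fisher_exact(tab)
        assert p == 1.0 and math.isnan(or_)

    def test_year_mix_shift_gives_or_below_one(self):
        """Sentiment mixes (0.5, 0.3, 0.2) in the first year and
        (0.1, 0.3, 0.6) in the second make negative-vs-positive odds
        fall: with the later year as the first row, the sample OR is
        < 1 in essentially every seed."""
        months = ([(f"2020-{m:02d}", 100 / 12) for m in range(1, 13)]
                  + [(f"2021-{m:02d}", 100 / 12) for m in range(1, 13)])
        below = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = CorpusSimConfig(
                months=months,
                sentiment_mix={2020: (0.5, 0.3, 0.2), 2021: (0.1, 0.3, 0.6)},
                mean_words=5.0, seed=seed)
            corpus = generate_corpus(cfg)
            tab = sentiment_contingency(corpus, "2021", "2020")
            or_, _ = fisher_exact(tab)
            if or_ < 1:
                below += 1
        assert below >= 0.99 * n_seeds


class TestLDA:
    def test_k1_matches_smoothed_unigram(self):
        docs = [["alpha", "beta", "alpha"], ["beta", "gamma"]]
        model = lda_fit(docs, k=1, iterations=5, seed=0, stopwords=())
        counts = np.array([2, 2, 1], dtype=float)  # alpha, beta, gamma
        beta = model.beta
        expected = (counts + beta) / (counts.sum() + 3 * beta)
        np.testing.assert_allclose(model.phi[0], expected, rtol=1e-12)

    def test_rows_are_distributions(self, two_topic_corpus):
        model = lda_fit(two_topic_corpus, k=2, iterations=60, seed=1)
        np.testing.assert_allclose(model.phi.sum(axis=1), 1, rtol=1e-9)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1, rtol=1e-9)

    def test_seed_determinism(self, two_topic_corpus):
        m1 = lda_fit(two_topic_corpus, k=2, iterations=30, seed=3)
        m2 = lda_fit(two_topic_corpus, k=2, iterations=30, seed=3)
        np.testing.assert_array_equal(m1.phi, m2.phi)
        np.testing.assert_array_equal(m1.theta, m2.theta)

    def test_disjoint_vocabulary_recovery(self, two_topic_corpus):
        """Two disjoint topic vocabularies are recovered with document
        purity >= 0.9."""
        model = lda_fit(two_topic_corpus, k=2, iterations=150, seed=2)
        truth = two_topic_corpus.posts["topic"].to_numpy()
        assigned = model.doc_topics()
        # best of the two label mappings
        acc = max(np.mean(assigned == truth), np.mean(assigned == 1 - truth))
        assert acc >= 0.9

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            lda_fit([["the", "and"]], k=2, iterations=5, seed=0)

    def test_log_likelihood_improves_over_burnin(self, two_topic_corpus):
        model = lda_fit(two_topic_corpus, k=2, iterations=100, seed=4)
        assert model.log_likelihood[-1] > model.log_likelihood[0]
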