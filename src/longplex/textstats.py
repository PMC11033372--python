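"""Temporal text analytics: activity, word frequencies, sentiment
contrasts, and a collapsed-Gibbs LDA topic model.

Sentiment labels are an *input* (attached to posts by any external
labeler); this module only aggregates and compares them. The Fisher
exact test uses the conventional two-sided probability-mass rule and
the sample (cross-product) odds-ratio estimator; a conditional-MLE
odds ratio is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_TOKEN_RE = re.compile(r"[\w']+", re.UNICODE)

#: Small general-purpose English stopword list; callers may pass their own.
DEFAULT_STOPWORDS = frozenset("""
a about above after again all am an and any are as at be because been
before being below between both but by can did do does doing down
during each few for from further had has have having he her here hers
him his how i if in into is it its itself just me more most my myself
no nor not now of off on once only or other our ours out over own s
same she should so some such t than that the their theirs them then
there these they this those through to too under until up very was we
were what when where which while who whom why will with you your yours
""".split())


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; possessive 's stripped; digits kept."""
    toks = _TOKEN_RE.findall(text.lower())
    out = []
    for t in toks:
        if t.endswith("'s"):
            t = t[:-2]
        t = t.strip("'")
        if t:
            out.append(t)
    return out


def activity_series(corpus, period: str = "month", date_range: tuple | None = None) -> pd.DataFrame:
    """Post count, mean words per post, and assisted-post count per period.

    Periods with no posts are zero-filled across ``date_range`` (default:
    first to last post). ``period`` is "month" or "year".
    """
    freq = {"month": "M", "year": "Y"}[period]
    posts = corpus.posts
    if len(posts) == 0 and date_range is None:
        return pd.DataFrame(columns=["period", "n_posts", "mean_words", "n_assisted"])
    periods = posts["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period(freq)
    grouped = posts.assign(period=periods).groupby("period")
    agg = grouped.agg(
        n_posts=("text", "size"),
        mean_words=("word_count", "mean"),
        n_assisted=("assisted", "sum"),
    )
    if date_range is not None:
        start, end = (pd.Period(d, freq=freq) for d in date_range)
    else:
        start, end = agg.index.min(), agg.index.max()
    full = pd.period_range(start, end, freq=freq)
    agg = agg.reindex(full)
    agg["n_posts"] = agg["n_posts"].fillna(0).astype(int)
    agg["n_assisted"] = agg["n_assisted"].fillna(0).astype(int)
    agg.index.name = "period"
    return agg.reset_index()


def word_frequencies(
    corpus,
    period: str | None = None,
    top_k: int | None = None,
    stopwords=DEFAULT_STOPWORDS,
) -> pd.DataFrame:
    """Ranked token counts, overall or per month/year.

    Counts are over lowercased, punctuation-stripped tokens with
    stopwords removed; ranking is by descending count with a stable
    alphabetical tie-break.
    """
    posts = corpus.posts
    stop = set(stopwords or ())
    rows = []
    if period is None:
        keys = pd.Series(["all"] * len(posts), index=posts.index)
    else:
        freq = {"month": "M", "year": "Y"}[period]
        keys = posts["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period(freq).astype(str)
    for key, chunk in posts.groupby(keys):
        counts: dict[str, int] = {}
        for text in chunk["text"].fillna(""):
            for tok in tokenize(text):
                if tok not in stop:
                    counts[tok] = counts.get(tok, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_k is not None:
            ranked = ranked[:top_k]
        for rank, (term, count) in enumerate(ranked, start=1):
            rows.append({"period": key, "rank": rank, "term": term, "count": count})
    return pd.DataFrame(rows, columns=["period", "rank", "term", "count"])


@dataclass(frozen=True)
class SentimentContingency:
    """2x2 table: rows = two periods, columns = two sentiment classes."""

    period_a: str
    period_b: str
    categories: tuple[str, str]
    a: int  # period_a, category 1
    b: int  # period_a, category 2
    c: int  # period_b, category 1
    d: int  # period_b, category 2

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def zero_margin(self) -> bool:
        t = self.as_array()
        return bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())


def sentiment_contingency(
    corpus,
    period_a: str,
    period_b: str,
    pair: tuple[str, str] = ("negative", "positive"),
) -> SentimentContingency:
    """Count posts of two sentiment classes in two periods (years or
    months); posts of the remaining class are excluded."""
    posts = corpus.posts.dropna(subset=["sentiment"])
    if len(posts) == 0:
        raise ValueError("corpus has no sentiment labels")
    freq = "Y" if len(str(period_a)) == 4 else "M"
    keys = posts["timestamp"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period(freq).astype(str)
    counts = {}
    for period in (str(period_a), str(period_b)):
        sel = posts[keys == period]
        counts[period] = [int((sel["sentiment"] == cat).sum()) for cat in pair]
    return SentimentContingency(
        period_a=str(period_a), period_b=str(period_b), categories=pair,
        a=counts[str(period_a)][0], b=counts[str(period_a)][1],
        c=counts[str(period_b)][0], d=counts[str(period_b)][1],
    )


def fisher_exact(table, conditional_or: bool = False) -> tuple[float, float]:
    """Fisher exact test on a 2x2 table.

    Returns (odds ratio, two-sided p). The p-value sums hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's. The odds ratio is
    the sample estimator a*d / (b*c) (inf when b*c = 0 with nonzero
    margins); ``conditional_or`` switches to the conditional MLE. A
    zero margin gives p = 1 and an undefined (NaN) odds ratio.
    """
    if isinstance(table, SentimentContingency):
        t = table.as_array()
    else:
        t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    (a, b), (c, d) = t
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if conditional_or:
        or_ = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    else:
        or_ = float(a * d / (b * c)) if b * c > 0 else float("inf")
    return or_, float(p)


@dataclass
class TopicModel:
    """Fitted LDA model: topic-word (phi) and document-topic (theta)
    distributions, plus the vocabulary and sampler settings."""

    k: int
    phi: np.ndarray      # K x V, rows sum to 1
    theta: np.ndarray    # D x K, rows sum to 1
    vocabulary: list[str]
    iterations: int
    seed: int
    alpha: float
    beta: float
    log_likelihood: list[float]

    def top_words(self, topic: int, n: int = 10) -> list[str]:
        order = np.argsort(-self.phi[topic])[:n]
        return [self.vocabulary[i] for i in order]

    def doc_topics(self) -> np.ndarray:
        return np.argmax(self.theta, axis=1)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "alpha": self.alpha, "beta": self.beta,
            "iterations": self.iterations, "seed": self.seed,
            "vocabulary": self.vocabulary,
            "phi": self.phi.tolist(), "theta": self.theta.tolist(),
        }


def lda_fit(
    corpus,
    k: int,
    iterations: int = 1000,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    stopwords=DEFAULT_STOPWORDS,
) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling with symmetric priors.

    ``alpha`` defaults to 50/K. phi and theta are posterior means from
    the final-iteration count matrices. Deterministic for a fixed seed.
    ``corpus`` may be a PostCorpus or a list of pre-tokenized documents.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if alpha is None:
        alpha = 50.0 / k
    if hasattr(corpus, "posts"):
        raw_docs = [tokenize(t) for t in corpus.posts["text"].fillna("")]
    else:
        raw_docs = [list(doc) for doc in corpus]
    stop = set(stopwords or ())
    docs = [[w for w in doc if w not in stop] for doc in raw_docs]
    docs = [doc for doc in docs if doc]
    if not docs:
        raise ValueError("empty vocabulary after stopword removal")
    vocab = sorted({w for doc in docs for w in doc})
    word_id = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)
    d_n = len(docs)

    rng = np.random.default_rng(seed)
    # flatten tokens for fast iteration
    doc_of: list[int] = []
    tok: list[int] = []
    for di, doc in enumerate(docs):
        for w in doc:
            doc_of.append(di)
            tok.append(word_id[w])
    doc_of_arr = np.array(doc_of)
    tok_arr = np.array(tok)
    n_tokens = len(tok_arr)

    z = rng.integers(0, k, size=n_tokens)
    n_dk = np.zeros((d_n, k))
    n_kw = np.zeros((k, v))
    n_k = np.zeros(k)
    np.add.at(n_dk, (doc_of_arr, z), 1)
    np.add.at(n_kw, (z, tok_arr), 1)
    np.add.at(n_k, z, 1)

    loglik: list[float] = []
    for it in range(iterations):
        u = rng.random(n_tokens)
        for i in range(n_tokens):
            di, wi, zi = doc_of_arr[i], tok_arr[i], z[i]
            n_dk[di, zi] -= 1
            n_kw[zi, wi] -= 1
            n_k[zi] -= 1
            probs = (n_kw[:, wi] + beta) / (n_k + v * beta) * (n_dk[di] + alpha)
            cum = np.cumsum(probs)
            zn = int(np.searchsorted(cum, u[i] * cum[-1]))
            z[i] = zn
            n_dk[di, zn] += 1
            n_kw[zn, wi] += 1
            n_k[zn] += 1
        if it % 10 == 0 or it == iterations - 1:
            phi_now = (n_kw + beta) / (n_k[:, None] + v * beta)
            theta_now = (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + k * alpha)
            ll = float(np.sum(np.log((theta_now[doc_of_arr] *
                                      phi_now[:, tok_arr].T).sum(axis=1))))
            loglik.append(ll)

    phi = (n_kw + beta) / (n_k[:, None] + v * beta)
    theta = (n_dk + alpha) / (n_dk.sum(axis=1, keepdims=True) + k * alpha)
    return TopicModel(k=k, phi=phi, theta=theta, vocabulary=vocab,
                      iterations=iterations, seed=seed, alpha=alpha,
                      beta=beta, log_likelihood=loglik)
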