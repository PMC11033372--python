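"""Dated text corpus of patient-authored posts.

Posts carry a timezone-aware timestamp (normalized to a single zone),
the text, an optional sentiment label in {negative, neutral, positive}
supplied by an external labeler, and a flag for assisted authorship.
Word counts are derived with the package tokenizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from longplex.textstats import tokenize

SENTIMENTS = ("negative", "neutral", "positive")


@dataclass
class PostCorpus:
    """Corpus of dated posts with derived per-post word counts."""

    posts: pd.DataFrame  # columns: timestamp, text, sentiment, assisted, word_count

    def __post_init__(self) -> None:
        df = self.posts.copy()
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        df["timestamp"] = ts
        if "sentiment" not in df:
            df["sentiment"] = pd.NA
        bad = df["sentiment"].dropna()
        bad = bad[~bad.isin(SENTIMENTS)]
        if len(bad):
            raise ValueError(f"unknown sentiment labels: {sorted(bad.unique())}")
        if "assisted" not in df:
            df["assisted"] = False
        df["assisted"] = df["assisted"].fillna(False).astype(bool)
        df["word_count"] = [len(tokenize(t)) for t in df["text"].fillna("")]
        self.posts = df.sort_values("timestamp").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.posts)

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "PostCorpus":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return cls(pd.DataFrame(rows))

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.posts.iterrows():
                rec = {
                    "timestamp": row["timestamp"].isoformat(),
                    "text": row["text"],
                    "assisted": bool(row["assisted"]),
                }
                if pd.notna(row["sentiment"]):
                    rec["sentiment"] = row["sentiment"]
                if "topic" in row.index and pd.notna(row.get("topic")):
                    rec["topic"] = int(row["topic"])
                fh.write(json.dumps(rec) + "\n")
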