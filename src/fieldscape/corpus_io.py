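"""Corpus ingestion: JSONL documents, tokenization/stemming, vocabulary
construction with document-frequency filters, and the sparse
document-term matrix.

A corpus is a list of :class:`Document` records, each tagged a priori
with one of two fields (``ecology`` or ``conservation``).  Text is
lowercased, split on non-alphabetic characters, stripped of one-letter
and numeric tokens, and Porter-stemmed.  The vocabulary keeps stems
whose document frequency lies within configurable bounds (stems at the
boundary are retained), and columns are ordered lexicographically so
every downstream matrix is reproducible.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .porter import porter_stem

logger = logging.getLogger(__name__)

FIELDS = ("ecology", "conservation")

_TOKEN_RE = re.compile(r"[a-z]+")


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid filter settings."""


@dataclass
class Document:
    """One article: identity, journal, a-priori field label, year, text."""

    id: str
    journal: str
    field: str
    year: int
    text: str = ""
    title: str | None = None
    tokens: list[str] | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.field not in FIELDS:
            raise CorpusError(
                f"document {self.id!r}: field must be one of {FIELDS}, got {self.field!r}"
            )

    def stems(self) -> list[str]:
        """Stemmed tokens, computed from text on first use and cached."""
        if self.tokens is None:
            self.tokens = tokenize_and_stem(self.text)
        return self.tokens


@dataclass
class Vocabulary:
    """Ordered stem list with document frequencies and a stem->column index."""

    stems: list[str]
    doc_frequency: dict[str, int]

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.stems)}
        if len(self.index) != len(self.stems):
            raise CorpusError("duplicate stems in vocabulary")

    def __len__(self) -> int:
        return len(self.stems)

    def __contains__(self, stem: str) -> bool:
        return stem in self.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stem": self.stems, "doc_frequency": [self.doc_frequency[s] for s in self.stems]}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Vocabulary":
        df = pd.read_csv(path)
        return cls(list(df["stem"]), dict(zip(df["stem"], df["doc_frequency"])))


def tokenize_and_stem(text: str) -> list[str]:
    """Lowercase, split on non-alphabetic runs, drop one-letter tokens,
    and Porter-stem each survivor (order preserved)."""
    return [porter_stem(t) for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2]


def load_corpus(path: str | Path) -> list[Document]:
    """Read a JSONL corpus (one object per line).

    A missing required key raises a per-record error naming the line;
    a duplicate id is fatal.
    """
    required = ("id", "journal", "field", "year", "text")
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            missing = [k for k in required if k not in rec]
            if missing:
                raise CorpusError(f"line {lineno}: missing required key(s) {missing}")
            if rec["id"] in seen:
                raise CorpusError(f"line {lineno}: duplicate document id {rec['id']!r}")
            seen.add(rec["id"])
            docs.append(
                Document(
                    id=str(rec["id"]),
                    journal=str(rec["journal"]),
                    field=str(rec["field"]),
                    year=int(rec["year"]),
                    text=str(rec["text"]),
                    title=rec.get("title"),
                )
            )
    logger.info("loaded %d documents from %s", len(docs), path)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSONL, inverse of :func:`load_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"id": d.id, "journal": d.journal, "field": d.field,
                   "year": d.year, "title": d.title, "text": d.text}
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def build_vocabulary(
    docs: Sequence[Document], min_df: float = 0.001, max_df: float = 0.80
) -> Vocabulary:
    """Stems kept iff min_df*D <= document frequency <= max_df*D.

    Document frequency is counted on stems (post-stemming).  The bounds
    are inclusive: a stem exactly at either threshold survives.
    """
    if not docs:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    if not (0 <= min_df < max_df <= 1):
        raise CorpusError(f"need 0 <= min_df < max_df <= 1, got ({min_df}, {max_df})")
    D = len(docs)
    df_counts: Counter[str] = Counter()
    for d in docs:
        df_counts.update(set(d.stems()))
    lo, hi = min_df * D, max_df * D
    kept = sorted(s for s, f in df_counts.items() if lo <= f <= hi)
    if not kept:
        raise CorpusError(
            f"vocabulary empty after filtering: D={D}, min_df={min_df} (>= {lo:.2f} docs), "
            f"max_df={max_df} (<= {hi:.2f} docs), {len(df_counts)} candidate stems"
        )
    return Vocabulary(kept, {s: df_counts[s] for s in kept})


def vectorize(docs: Sequence[Document], vocab: Vocabulary) -> sp.csr_matrix:
    """D x V sparse count matrix; out-of-vocabulary stems are dropped."""
    if len(vocab) == 0:
        raise CorpusError("empty vocabulary")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for i, d in enumerate(docs):
        counts = Counter(d.stems())
        in_vocab = False
        for stem, c in counts.items():
            j = vocab.index.get(stem)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
                in_vocab = True
        if counts and not in_vocab:
            logger.warning("document %s has no in-vocabulary stems", d.id)
    X = sp.csr_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)),
        shape=(len(docs), len(vocab)),
    )
    X.sum_duplicates()
    return X


def articles_per_year(docs: Sequence[Document]) -> pd.DataFrame:
    """Counts by (year, field); rows partition the corpus."""
    if not docs:
        return pd.DataFrame(columns=["year", "field", "count"])
    df = pd.DataFrame({"year": [d.year for d in docs], "field": [d.field for d in docs]})
    out = df.value_counts(["year", "field"]).rename("count").reset_index()
    return out.sort_values(["year", "field"], ignore_index=True)


def corpus_frame(docs: Sequence[Document]) -> pd.DataFrame:
    """Metadata table (id, journal, field, year) in corpus order."""
    return pd.DataFrame(
        {
            "id": [d.id for d in docs],
            "journal": [d.journal for d in docs],
            "field": [d.field for d in docs],
            "year": [d.year for d in docs],
        }
    )


def write_matrix(X: sp.spmatrix, path: str | Path) -> None:
    from scipy.io import mmwrite

    mmwrite(str(path), X)


def read_matrix(path: str | Path) -> sp.csr_matrix:
    from scipy.io import mmread

    return sp.csr_matrix(mmread(str(path)))
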