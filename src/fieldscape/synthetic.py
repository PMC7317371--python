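"""Synthetic two-field corpora with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so that every downstream statistic can be checked against a
planted truth:

* two fields (``ecology``, ``conservation``) drawing documents from a
  shared k-topic model;
* field-biased Dirichlet topic priors — each field concentrates on its
  own set of biased topics;
* a quadratic drift of conservation's concentration on ecology-biased
  topics, symmetric about a configurable peak year (default 2005) and
  continuing below baseline toward the end of the range, so the
  ecology content of conservation documents rises, peaks, then
  declines well below its starting level;
* a slow linear rise of conservation's concentration on its own
  biased topics (increasing specialization of the field);
* geometric corpus growth over the year range;
* citations whose cross-field probability decays with the Hellinger
  distance between the citing and cited topic mixtures, damped by an
  assortativity factor, with most references left unresolvable to
  mimic real within-corpus resolution rates (~8%).

Vocabulary symbols are consonant-only strings (no vowels, no ``s``,
no ``y``), which are fixed points of the Porter stemmer and survive
tokenization unchanged, so a written corpus re-ingested through
`corpus_io` reproduces the planted counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .citations import CitationRecord
from .corpus_io import Document

_ALPHABET = "bcdfghjklmnpqrtvwz"  # consonant-only: Porter-stable symbols


def word_symbol(i: int) -> str:
    """Base-18 consonant string for vocabulary index i (3 letters)."""
    n = len(_ALPHABET)
    if not 0 <= i < n ** 3:
        raise ValueError(f"symbol index {i} out of range")
    return _ALPHABET[i // (n * n)] + _ALPHABET[(i // n) % n] + _ALPHABET[i % n]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a generated corpus."""

    k: int = 10
    V: int = 500
    phi_true: np.ndarray | None = None          # k x V, rows sum to 1
    eco_biased: tuple = ()
    cons_biased: tuple = ()
    year_min: int = 2000
    year_max: int = 2014
    peak_year: int = 2005
    amplitude: float = 0.5                      # relative drift of eco mass in conservation
    growth_rate: float = 1.03                   # per-year corpus growth factor
    assortativity: float = 0.7                  # 0: field-blind, 1: no cross-field citations
    distance_scale: float = 0.3                 # Hellinger decay scale of the citation kernel
    alpha_shared: float = 0.5
    alpha_own: float = 2.0
    alpha_other: float = 0.15
    cons_specialization: float = 0.03           # linear rise/yr of conservation's own-topic mass
    specialization_rate: float = 0.0            # >0: conservation homogenizes after peak_year
    seed: int = 0

    def drift_multiplier(self, year: int) -> float:
        """Quadratic concentration multiplier on conservation's
        ecology-biased topics: 1 + A at the peak, 1 at year_min, and
        continuing below baseline after the mirror year (floored at 0.1
        so concentrations stay positive)."""
        span = max(1, self.peak_year - self.year_min)
        u = (year - self.peak_year) / span
        return max(0.1, 1.0 + self.amplitude * (1.0 - u * u))

    def alpha_field(self, field: str, year: int) -> np.ndarray:
        """Per-topic Dirichlet concentration for one field and year."""
        alpha = np.full(self.k, self.alpha_shared)
        if field == "ecology":
            alpha[list(self.eco_biased)] = self.alpha_own
            alpha[list(self.cons_biased)] = self.alpha_other
        elif field == "conservation":
            rise = 1.0 + self.cons_specialization * (year - self.year_min)
            alpha[list(self.cons_biased)] = self.alpha_own * rise
            alpha[list(self.eco_biased)] = self.alpha_other * self.drift_multiplier(year)
            if self.specialization_rate > 0 and year > self.peak_year:
                g = 1.0 + self.specialization_rate * (year - self.peak_year)
                own = list(self.cons_biased)
                rest = [t for t in range(self.k) if t not in self.cons_biased]
                alpha[own] *= g
                alpha[rest] /= g
        else:
            raise ValueError(f"unknown field {field!r}")
        return alpha


def make_truth(k: int = 10, V: int = 500, n_biased_per_field: int = 3,
               phi_concentration: float = 0.05, seed: int = 0,
               **overrides) -> SyntheticTruth:
    """Draw topic-word distributions and fix the planted structure.

    Topics 0..n-1 are ecology-biased, the next n conservation-biased,
    the rest shared.  φ rows come from a sparse symmetric Dirichlet so
    topics have distinct, heavy-tailed word profiles.
    """
    if k < 2 or V < k:
        raise ValueError("need k >= 2 and V >= k")
    if 2 * n_biased_per_field > k:
        raise ValueError("2 * n_biased_per_field must not exceed k")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, phi_concentration), size=k)
    truth = SyntheticTruth(
        k=k, V=V, phi_true=phi,
        eco_biased=tuple(range(n_biased_per_field)),
        cons_biased=tuple(range(n_biased_per_field, 2 * n_biased_per_field)),
        seed=seed, **overrides,
    )
    if truth.alpha_shared <= 0 or truth.alpha_own <= 0 or truth.alpha_other <= 0:
        raise ValueError("all Dirichlet concentrations must be positive")
    return truth


@dataclass
class SyntheticCorpus:
    documents: list  # corpus_io.Document
    theta_true: np.ndarray  # D x k
    truth: SyntheticTruth
    citations: list = dc_field(default_factory=list)
    true_edges: pd.DataFrame | None = None

    @property
    def field_labels(self) -> dict[str, str]:
        return {d.id: d.field for d in self.documents}

    @property
    def years(self) -> np.ndarray:
        return np.array([d.year for d in self.documents])

    @property
    def fields(self) -> np.ndarray:
        return np.array([d.field for d in self.documents])


def generate_corpus(truth: SyntheticTruth, docs_per_field_year_base: int = 54,
                    doc_length_mean: float = 300.0, seed: int = 0) -> SyntheticCorpus:
    """Sample documents year by year from the planted topic model.

    Per document: θ ~ Dirichlet(alpha_field(field, year)), length ~
    Poisson(doc_length_mean), token topic ~ θ, token word ~ φ_topic.
    Yearly document counts per field grow geometrically.
    """
    if docs_per_field_year_base < 1:
        raise ValueError("docs_per_field_year_base must be >= 1")
    if doc_length_mean < 20:
        raise ValueError("doc_length_mean must be >= 20")
    rng = np.random.default_rng(seed)
    words = [word_symbol(i) for i in range(truth.V)]
    docs: list[Document] = []
    thetas: list[np.ndarray] = []
    for year in range(truth.year_min, truth.year_max + 1):
        n_year = max(1, round(docs_per_field_year_base
                              * truth.growth_rate ** (year - truth.year_min)))
        for field in ("ecology", "conservation"):
            alpha = truth.alpha_field(field, year)
            for j in range(n_year):
                theta = rng.dirichlet(alpha)
                length = rng.poisson(doc_length_mean)
                topic_counts = rng.multinomial(length, theta)
                word_counts = np.zeros(truth.V, dtype=np.int64)
                for t in np.nonzero(topic_counts)[0]:
                    word_counts += rng.multinomial(topic_counts[t], truth.phi_true[t])
                tokens = [words[w] for w in np.repeat(np.arange(truth.V), word_counts)]
                doc_id = f"{field[:3]}-{year}-{j:04d}"
                docs.append(Document(
                    id=doc_id,
                    journal=f"{field}-journal-{j % 2}",
                    field=field, year=year,
                    title=f"Synthetic article {doc_id}",
                    text=" ".join(tokens),
                    tokens=tokens,
                ))
                thetas.append(theta)
    return SyntheticCorpus(documents=docs, theta_true=np.vstack(thetas), truth=truth)


def hellinger_rows(theta: np.ndarray) -> np.ndarray:
    """Pairwise Hellinger distance matrix between rows of θ."""
    root = np.sqrt(theta)
    bc = np.clip(root @ root.T, 0.0, 1.0)
    return np.sqrt(np.clip(1.0 - bc, 0.0, None))


def generate_citations(corpus: SyntheticCorpus, refs_per_doc_mean: float = 30.0,
                       resolvable_fraction: float = 0.08, seed: int = 0):
    """Sample bibliographies for every document.

    Resolvable references cite an earlier-or-same-year document with
    probability ∝ exp(−Hellinger(θ_i, θ_j) / distance_scale), damped by
    (1 − assortativity) across fields; the rest are external strings
    that cannot resolve.  Populates ``corpus.citations`` and
    ``corpus.true_edges`` and returns the record list.
    """
    truth = corpus.truth
    rng = np.random.default_rng(seed)
    D = len(corpus.documents)
    if D == 0:
        raise ValueError("empty corpus")
    years = corpus.years
    fields = corpus.fields
    ids = [d.id for d in corpus.documents]
    H = hellinger_rows(corpus.theta_true)
    kernel = np.exp(-H / truth.distance_scale)
    records: list[CitationRecord] = []
    edges = []
    ext = 0
    for i in range(D):
        n_refs = rng.poisson(refs_per_doc_mean)
        n_resolved = rng.binomial(n_refs, resolvable_fraction)
        eligible = np.flatnonzero(years <= years[i])
        eligible = eligible[eligible != i]
        if eligible.size == 0:
            n_resolved = 0
        w = None
        if n_resolved:
            w = kernel[i, eligible].copy()
            w[fields[eligible] != fields[i]] *= 1.0 - truth.assortativity
            total = w.sum()
            if total <= 0:
                n_resolved = 0
            else:
                w /= total
        for _ in range(n_resolved):
            j = int(eligible[rng.choice(eligible.size, p=w)])
            records.append(CitationRecord(
                citing_id=ids[i],
                target_doi=f"10.5555/{ids[j]}",
                target_title=corpus.documents[j].title,
            ))
            edges.append((ids[i], ids[j]))
        for _ in range(n_refs - n_resolved):
            records.append(CitationRecord(
                citing_id=ids[i],
                target_doi=f"10.9999/external-{ext}",
                target_title=f"External reference {ext}",
            ))
            ext += 1
    corpus.citations = records
    corpus.true_edges = pd.DataFrame(edges, columns=["citing_id", "cited_id"])
    return records


def references_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "citing_id": [r.citing_id for r in records],
            "target_doi": [r.target_doi for r in records],
            "target_title": [r.target_title for r in records],
        }
    )


def save_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {k: v for k, v in truth.__dict__.items() if k != "phi_true"}
    meta["eco_biased"] = list(truth.eco_biased)
    meta["cons_biased"] = list(truth.cons_biased)
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    np.save(directory / "phi_true.npy", truth.phi_true)


def load_truth(directory: str | Path) -> SyntheticTruth:
    directory = Path(directory)
    with open(directory / "truth.yaml") as fh:
        meta = yaml.safe_load(fh)
    meta["eco_biased"] = tuple(meta["eco_biased"])
    meta["cons_biased"] = tuple(meta["cons_biased"])
    return SyntheticTruth(phi_true=np.load(directory / "phi_true.npy"), **meta)
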