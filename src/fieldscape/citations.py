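"""Citation-network construction and cross-field statistics.

Bibliography entries carry a DOI and/or a title.  Resolution against
the corpus tries the DOI first, then a normalized title (lowercased,
all non-alphanumerics removed); entries matching neither — the large
majority in real bibliometric corpora — stay unresolved.  Resolved
entries become a directed citation graph from which we compute the
2x2 citing-field x cited-field table, the share of references that
stay within the corpus, and each article's cross-field in-citation
count (used to weight density landscapes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

_NORM_RE = re.compile(r"[^a-z0-9]+")


def normalize_title(title: str) -> str:
    """Lowercase and strip every non-alphanumeric character."""
    return _NORM_RE.sub("", title.lower())


@dataclass
class CitationRecord:
    """One bibliography entry of a corpus article."""

    citing_id: str
    target_doi: str | None = None
    target_title: str | None = None
    resolved_id: str | None = None
    resolved_by: str = "none"  # doi | title | none
    ambiguous: bool = False


@dataclass
class CorpusIndex:
    """DOI -> id and normalized-title -> id lookup for the corpus."""

    by_doi: dict[str, str]
    by_title: dict[str, str]
    ambiguous_titles: set[str] = field(default_factory=set)

    @classmethod
    def build(cls, ids, dois=None, titles=None) -> "CorpusIndex":
        by_doi: dict[str, str] = {}
        by_title: dict[str, str] = {}
        ambiguous: set[str] = set()
        for i, doc_id in enumerate(ids):
            if dois is not None and dois[i]:
                by_doi[dois[i]] = doc_id
            if titles is not None and titles[i]:
                key = normalize_title(titles[i])
                if key in by_title and by_title[key] != doc_id:
                    ambiguous.add(key)
                else:
                    by_title[key] = doc_id
        for key in ambiguous:
            by_title.pop(key, None)
        return cls(by_doi, by_title, ambiguous)


def resolve_citations(records: list[CitationRecord], index: CorpusIndex) -> list[CitationRecord]:
    """Resolve in place-order: exact DOI, else normalized title, else none.

    A title that normalizes to a key shared by several corpus articles
    is left unresolved and flagged ambiguous.
    """
    out = []
    for rec in records:
        resolved_id, how, ambiguous = None, "none", False
        if rec.target_doi and rec.target_doi in index.by_doi:
            resolved_id, how = index.by_doi[rec.target_doi], "doi"
        elif rec.target_title:
            key = normalize_title(rec.target_title)
            if key in index.ambiguous_titles:
                ambiguous = True
            elif key in index.by_title:
                resolved_id, how = index.by_title[key], "title"
        out.append(
            CitationRecord(rec.citing_id, rec.target_doi, rec.target_title,
                           resolved_id, how, ambiguous)
        )
    return out


def citation_edges(resolved: list[CitationRecord]) -> pd.DataFrame:
    """Deduplicated resolved edge list, self-citations excluded."""
    rows = [
        {"citing_id": r.citing_id, "cited_id": r.resolved_id, "resolved_by": r.resolved_by}
        for r in resolved
        if r.resolved_id is not None and r.resolved_id != r.citing_id
    ]
    edges = pd.DataFrame(rows, columns=["citing_id", "cited_id", "resolved_by"])
    return edges.drop_duplicates(["citing_id", "cited_id"], ignore_index=True)


@dataclass
class CrossFieldStats:
    """Citing-field x cited-field counts with row percentages and totals."""

    table: pd.DataFrame          # 2x2 counts, rows = citing field
    row_percent: pd.DataFrame    # rows sum to 100
    n_references: int            # all bibliography entries
    n_resolved: int              # entries resolved into the corpus
    cross_total: int             # off-diagonal edge count

    @property
    def resolved_fraction(self) -> float:
        return self.n_resolved / self.n_references if self.n_references else np.nan


def resolved_fraction(n_references: int, n_resolved: int) -> float:
    """Share of bibliography entries that resolve to in-corpus articles."""
    if n_resolved > n_references:
        raise ValueError("resolved count exceeds total references")
    return n_resolved / n_references


def cross_field_stats(edges: pd.DataFrame, field_labels: dict[str, str],
                      n_references: int | None = None) -> CrossFieldStats:
    """2x2 citation table by field with row percentages.

    `n_references` is the total bibliography size (resolved plus
    unresolved); it defaults to the edge count when not supplied.
    """
    fields = sorted(set(field_labels.values()))
    citing = edges["citing_id"].map(field_labels)
    cited = edges["cited_id"].map(field_labels)
    if citing.isna().any() or cited.isna().any():
        raise ValueError("edge endpoints missing field labels")
    table = (
        pd.crosstab(citing, cited)
        .reindex(index=fields, columns=fields, fill_value=0)
        .rename_axis(index="citing_field", columns="cited_field")
    )
    row_sums = table.sum(axis=1)
    row_percent = table.div(row_sums.replace(0, np.nan), axis=0) * 100
    n_resolved = int(table.values.sum())
    cross_total = int(table.values.sum() - np.trace(table.values))
    return CrossFieldStats(
        table=table,
        row_percent=row_percent,
        n_references=int(n_references) if n_references is not None else n_resolved,
        n_resolved=n_resolved,
        cross_total=cross_total,
    )


def cross_citation_weights(edges: pd.DataFrame, field_labels: dict[str, str],
                           all_ids) -> pd.Series:
    """Per-article count of resolved citations received from the other
    field (zero for never-cross-cited articles); indexed over all ids."""
    weights = pd.Series(0, index=pd.Index(all_ids, name="id"), dtype=int)
    if len(edges):
        cross = edges[
            edges["citing_id"].map(field_labels) != edges["cited_id"].map(field_labels)
        ]
        counts = cross["cited_id"].value_counts()
        common = counts.index.intersection(weights.index)
        weights.loc[common] = counts[common].astype(int)
    return weights


def top_cited_subgraph(edges: pd.DataFrame, field_labels: dict[str, str],
                       fraction: float = 0.05) -> nx.DiGraph:
    """Subgraph of the top `fraction` of articles by within-corpus
    in-degree (ties broken by id); node attribute ``cross_citations``
    counts cross-field in-citations within the full graph."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    cited_ids = pd.concat([edges["citing_id"], edges["cited_id"]]).unique()
    indeg = edges["cited_id"].value_counts().reindex(cited_ids, fill_value=0)
    ranked = indeg.sort_index().sort_values(ascending=False, kind="stable")
    n_top = max(1, int(round(fraction * len(ranked))))
    top = set(ranked.index[:n_top])
    weights = cross_citation_weights(edges, field_labels, sorted(top))
    g = nx.DiGraph()
    for node in sorted(top):
        g.add_node(node, cross_citations=int(weights[node]),
                   field=field_labels.get(node))
    sub = edges[edges["citing_id"].isin(top) & edges["cited_id"].isin(top)]
    g.add_edges_from(zip(sub["citing_id"], sub["cited_id"]))
    return g


def records_from_frame(df: pd.DataFrame) -> list[CitationRecord]:
    """Read raw references from a (citing_id, target_doi, target_title) table."""
    return [
        CitationRecord(
            citing_id=str(r.citing_id),
            target_doi=None if pd.isna(r.target_doi) else str(r.target_doi),
            target_title=None if pd.isna(r.target_title) else str(r.target_title),
        )
        for r in df.itertuples(index=False)
    ]
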