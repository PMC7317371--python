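"""Field-biased topic statistics.

Two complementary routes identify topics more prevalent in one field
than the other:

* the full-distribution route — per topic, the difference (delta) of
  median log10 topic probability between the two fields; positive
  delta means ecology-biased;
* the discretized route — an article is "about" a topic when its
  probability strictly exceeds a threshold τ (default 0.05); the ratio
  of the two fields' about-fractions is a relative risk (RR), with a
  Haldane–Anscombe continuity correction when a count is zero.

Medians use the lower-median convention for even-length samples so the
statistic is always an observed value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ECO, CONS = "ecology", "conservation"


def lower_median(values: np.ndarray) -> float:
    """Order statistic at index (n-1)//2 — the lower median."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(v[(v.size - 1) // 2])


def median_log_prob(theta: np.ndarray, field_labels) -> pd.DataFrame:
    """Per-topic, per-field medians of log10 θ and their delta (eco − cons)."""
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(field_labels)
    if labels.shape[0] != theta.shape[0]:
        raise ValueError("one field label per θ row required")
    rows = []
    for name in (ECO, CONS):
        mask = labels == name
        if not mask.any():
            raise ValueError(f"no articles labeled {name!r}")
        logt = np.log10(theta[mask])
        rows.append([lower_median(logt[:, t]) for t in range(theta.shape[1])])
    out = pd.DataFrame(
        {
            "topic": np.arange(theta.shape[1]),
            "median_log10_eco": rows[0],
            "median_log10_cons": rows[1],
        }
    )
    out["delta"] = out["median_log10_eco"] - out["median_log10_cons"]
    out["bias_class"] = np.select(
        [out["delta"] > 0, out["delta"] < 0], [ECO, CONS], default="neutral"
    )
    return out


def discretize(theta: np.ndarray, tau: float = 0.05) -> np.ndarray:
    """Boolean D x k "aboutness" matrix: θ strictly exceeding τ."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return np.asarray(theta) > tau


def relative_risk(about: np.ndarray, field_labels) -> pd.DataFrame:
    """Per-topic RR = about-fraction(eco) / about-fraction(cons).

    When either about-count is zero, 0.5 is added to both that topic's
    counts and both denominators (flagged in the ``corrected`` column).
    """
    about = np.asarray(about, dtype=bool)
    labels = np.asarray(field_labels)
    eco_mask, cons_mask = labels == ECO, labels == CONS
    if not eco_mask.any() or not cons_mask.any():
        raise ValueError("both fields must be represented")
    n_eco, n_cons = int(eco_mask.sum()), int(cons_mask.sum())
    a_eco = about[eco_mask].sum(axis=0).astype(float)
    a_cons = about[cons_mask].sum(axis=0).astype(float)
    corrected = (a_eco == 0) | (a_cons == 0)
    num = np.where(corrected, (a_eco + 0.5) / (n_eco + 0.5), a_eco / n_eco)
    den = np.where(corrected, (a_cons + 0.5) / (n_cons + 0.5), a_cons / n_cons)
    return pd.DataFrame(
        {
            "topic": np.arange(about.shape[1]),
            "about_frac_eco": a_eco / n_eco,
            "about_frac_cons": a_cons / n_cons,
            "rr": num / den,
            "corrected": corrected,
        }
    )


def field_bias_table(theta: np.ndarray, field_labels, tau: float = 0.05) -> pd.DataFrame:
    """Full per-topic bias table: medians, delta, about-fractions, RR, class."""
    med = median_log_prob(theta, field_labels)
    rr = relative_risk(discretize(theta, tau), field_labels)
    out = med.merge(rr, on="topic")
    out.attrs["tau"] = tau
    return out


def top_biased_topics(bias_table: pd.DataFrame, m: int = 10, method: str = "delta"):
    """The m most ecology-biased and m most conservation-biased topics.

    ``method`` ranks by median-delta (default) or by RR; the two sets
    are disjoint by construction.
    """
    k = len(bias_table)
    if not 1 <= m <= k // 2:
        raise ValueError("need 1 <= m <= k/2")
    if method == "delta":
        key = "delta"
    elif method == "rr":
        key = "rr"
    else:
        raise ValueError("method must be 'delta' or 'rr'")
    ranked = bias_table.sort_values([key, "topic"], ascending=[False, True])
    eco_set = set(ranked["topic"].head(m))
    cons_set = set(ranked["topic"].tail(m))
    return eco_set, cons_set


def bias_load(theta: np.ndarray, topic_set) -> np.ndarray:
    """Per-article summed probability over a nonempty topic set."""
    topics = sorted(topic_set)
    if not topics:
        raise ValueError("topic_set must be nonempty")
    return np.asarray(theta)[:, topics].sum(axis=1)


def count_about_articles(about: np.ndarray, topic_set, years, field_labels) -> pd.DataFrame:
    """Articles with at least one about-topic in the set, per year x field."""
    topics = sorted(topic_set)
    if not topics:
        raise ValueError("topic_set must be nonempty")
    hit = np.asarray(about, dtype=bool)[:, topics].any(axis=1)
    df = pd.DataFrame({"year": np.asarray(years), "field": np.asarray(field_labels), "hit": hit})
    out = (
        df.groupby(["year", "field"], as_index=False)["hit"]
        .sum()
        .rename(columns={"hit": "count"})
    )
    out["count"] = out["count"].astype(int)
    return out.sort_values(["year", "field"], ignore_index=True)
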