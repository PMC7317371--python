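import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fieldscape import corpus_io, field_bias, lda, synthetic

# Seeds for the planted-recovery replicates: replicate s uses truth seed
# 10s, corpus seed 10s+1, sampler seed 10s+2 and bootstrap seed 10s+3.
RECOVERY_SEEDS = (1, 2, 3)


def fit_drift_replicate(s: int) -> dict:
    """Generate the default drift corpus and fit LDA for replicate s."""
    base = 10 * s
    truth = synthetic.make_truth(seed=base)
    corpus = synthetic.generate_corpus(truth, seed=base + 1)
    vocab = corpus_io.build_vocabulary(corpus.documents, min_df=0.0, max_df=1.0)
    X = corpus_io.vectorize(corpus.documents, vocab)
    fit = lda.fit_lda(X, k=truth.k, seed=base + 2)
    return {"truth": truth, "corpus": corpus, "vocab": vocab, "X": X,
            "fit": fit, "seed": s}


@pytest.fixture(scope="session")
def drift_fits():
    """Three fitted replicates of the default drift corpus (heavy; shared)."""
    return {s: fit_drift_replicate(s) for s in RECOVERY_SEEDS}


def restricted_phi_true(truth, vocab) -> np.ndarray:
    """Planted topic-word rows restricted to the observed vocabulary
    columns and renormalized (words never drawn cannot be recovered)."""
    index = {synthetic.word_symbol(i): i for i in range(truth.V)}
    cols = [index[s] for s in vocab.stems]
    phi = truth.phi_true[:, cols]
    return phi / phi.sum(axis=1, keepdims=True)


def hellinger_match(phi_fit: np.ndarray, phi_true: np.ndarray):
    """Hungarian assignment of fitted to planted topics on Hellinger
    distance; returns (mean matched distance, true->fit topic map)."""
    bc = np.clip(np.sqrt(phi_fit) @ np.sqrt(phi_true).T, 0.0, 1.0)
    dist = np.sqrt(np.clip(1.0 - bc, 0.0, None))
    rows, cols = linear_sum_assignment(dist)
    fit_of_true = {int(t): int(rows[list(cols).index(t)]) for t in cols}
    return float(dist[rows, cols].mean()), fit_of_true


@pytest.fixture(scope="session")
def small_planted():
    """A small, fast planted corpus (k=3) for unit-level model tests."""
    truth = synthetic.make_truth(k=3, V=60, n_biased_per_field=1,
                                 phi_concentration=0.08, seed=77)
    corpus = synthetic.generate_corpus(truth, docs_per_field_year_base=4,
                                       doc_length_mean=300.0, seed=78)
    vocab = corpus_io.build_vocabulary(corpus.documents, min_df=0.0, max_df=1.0)
    X = corpus_io.vectorize(corpus.documents, vocab)
    fit = lda.fit_lda(X, k=3, n_iter=400, burn_in=200, seed=79)
    return {"truth": truth, "corpus": corpus, "vocab": vocab, "X": X, "fit": fit}


@pytest.fixture
def tiny_docs():
    """Six handmade documents, three per field, two journals each."""
    mk = corpus_io.Document
    return [
        mk(id="e1", journal="JE1", field="ecology", year=2001,
           text="forests forest forested stream streams"),
        mk(id="e2", journal="JE2", field="ecology", year=2001,
           text="stream ecology predation predator"),
        mk(id="e3", journal="JE1", field="ecology", year=2002,
           text="predators forests trait traits"),
        mk(id="c1", journal="JC1", field="conservation", year=2001,
           text="policy policies reserve reserves"),
        mk(id="c2", journal="JC2", field="conservation", year=2002,
           text="reserve management managing policy"),
        mk(id="c3", journal="JC1", field="conservation", year=2002,
           text="management extinction extinctions policy"),
    ]
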