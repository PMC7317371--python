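"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The corpus model: each document d mixes k topics through θ_d ~
Dirichlet(α), each topic t is a distribution φ_t over the V vocabulary
stems (φ_t ~ Dirichlet(β)), and every token is drawn by first picking a
topic from θ_d and then a stem from φ_t.  Collapsed Gibbs sampling
integrates θ and φ out analytically and resamples each token's topic
assignment from

    p(z = t | rest) ∝ (n_dt + α) (n_tw + β) / (n_t· + Vβ),

where the count tables exclude the token being resampled.  Point
estimates of φ and θ are smoothed averages of the post-burn-in count
tables, so every probability (and hence log10 θ) is finite.

`GibbsLDA` is a scikit-learn style estimator: ``fit`` on a sparse
document-term count matrix, ``transform`` folds new documents in with
φ held fixed, ``components_`` holds φ and ``doc_topic_`` holds θ.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sampling kernels


@njit(cache=True)
def _gibbs_sweep(doc_ids, word_ids, z, ndt, ntw, nt, alpha, beta, uniforms, probs):
    """One full sweep over all tokens, resampling each assignment in place."""
    k = nt.shape[0]
    V = ntw.shape[1]
    vbeta = V * beta
    for i in range(doc_ids.shape[0]):
        d = doc_ids[i]
        w = word_ids[i]
        t = z[i]
        ndt[d, t] -= 1
        ntw[t, w] -= 1
        nt[t] -= 1
        total = 0.0
        for tt in range(k):
            p = (ndt[d, tt] + alpha) * (ntw[tt, w] + beta) / (nt[tt] + vbeta)
            probs[tt] = p
            total += p
        r = uniforms[i] * total
        acc = 0.0
        tnew = k - 1
        for tt in range(k):
            acc += probs[tt]
            if r < acc:
                tnew = tt
                break
        z[i] = tnew
        ndt[d, tnew] += 1
        ntw[tnew, w] += 1
        nt[tnew] += 1


@njit(cache=True)
def _fold_in_sweep(word_ids, z, ndt_row, phi, alpha, uniforms, probs):
    """Sweep over one held-out document's tokens with φ fixed."""
    k = phi.shape[0]
    for i in range(word_ids.shape[0]):
        w = word_ids[i]
        t = z[i]
        ndt_row[t] -= 1
        total = 0.0
        for tt in range(k):
            p = (ndt_row[tt] + alpha) * phi[tt, w]
            probs[tt] = p
            total += p
        r = uniforms[i] * total
        acc = 0.0
        tnew = k - 1
        for tt in range(k):
            acc += probs[tt]
            if r < acc:
                tnew = tt
                break
        z[i] = tnew
        ndt_row[tnew] += 1


def gibbs_conditional(ndt_d, ntw_w, nt, alpha, beta, V):
    """Collapsed conditional p(z = t | rest) as a length-k vector.

    The current token's counts must already be decremented from the
    tables.  Raises on negative counts (an invariant breach upstream).
    """
    ndt_d = np.asarray(ndt_d, dtype=float)
    ntw_w = np.asarray(ntw_w, dtype=float)
    nt = np.asarray(nt, dtype=float)
    if (ndt_d < 0).any() or (ntw_w < 0).any() or (nt < 0).any():
        raise ValueError("negative counts in Gibbs state")
    p = (ndt_d + alpha) * (ntw_w + beta) / (nt + V * beta)
    return p / p.sum()


def _tokens_from_matrix(X: sp.spmatrix):
    """Flatten a count matrix into parallel (doc_id, word_id) token arrays."""
    X = sp.csr_matrix(X)
    coo = X.tocoo()
    reps = coo.data.astype(np.int64)
    doc_ids = np.repeat(coo.row.astype(np.int64), reps)
    word_ids = np.repeat(coo.col.astype(np.int64), reps)
    order = np.lexsort((word_ids, doc_ids))
    return doc_ids[order], word_ids[order]


def joint_log_likelihood(ndt, ntw, alpha, beta):
    """Collapsed joint log p(w, z) up to the constant multinomial terms."""
    D, k = ndt.shape
    V = ntw.shape[1]
    nd = ndt.sum(axis=1)
    nt = ntw.sum(axis=1)
    ll = D * (gammaln(k * alpha) - k * gammaln(alpha))
    ll += gammaln(ndt + alpha).sum() - gammaln(nd + k * alpha).sum()
    ll += k * (gammaln(V * beta) - V * gammaln(beta))
    ll += gammaln(ntw + beta).sum() - gammaln(nt + V * beta).sum()
    return ll


class GibbsLDA(BaseEstimator, TransformerMixin):
    """LDA fitted by collapsed Gibbs sampling.

    Parameters
    ----------
    n_topics : int
        Number of topics k.
    alpha : float or None
        Symmetric document-topic concentration; ``None`` uses 1/k.
    beta : float
        Symmetric topic-word concentration.
    n_iter, burn_in, thin : int
        Total sweeps, discarded sweeps, and the averaging stride for the
        post-burn-in count tables.
    random_state : int or None
        Seed for the sampler's uniform stream and initialization.

    Attributes
    ----------
    components_ : (k, V) array — φ, rows sum to 1.
    doc_topic_ : (D, k) array — θ, rows sum to 1.
    assignments_ : final per-token topic labels.
    log_likelihood_trace_ : per-sweep collapsed joint log-likelihood.
    """

    def __init__(self, n_topics=10, alpha=None, beta=0.01, n_iter=1500,
                 burn_in=1000, thin=10, random_state=None):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state

    def _effective_alpha(self):
        return 1.0 / self.n_topics if self.alpha is None else float(self.alpha)

    def fit(self, X, y=None):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        X = sp.csr_matrix(X)
        if X.nnz == 0:
            raise ValueError("empty document-term matrix")
        if (X.data < 0).any():
            raise ValueError("negative counts in document-term matrix")
        D, V = X.shape
        empty = np.asarray(X.sum(axis=1)).ravel() == 0
        if empty.any():
            logger.warning("%d all-zero document rows are skipped", int(empty.sum()))
        k = self.n_topics
        alpha = self._effective_alpha()
        beta = float(self.beta)
        rng = np.random.default_rng(self.random_state)

        doc_ids, word_ids = _tokens_from_matrix(X)
        n_tokens = doc_ids.shape[0]
        z = rng.integers(0, k, size=n_tokens).astype(np.int64)
        ndt = np.zeros((D, k), dtype=np.int64)
        ntw = np.zeros((k, V), dtype=np.int64)
        np.add.at(ndt, (doc_ids, z), 1)
        np.add.at(ntw, (z, word_ids), 1)
        nt = ntw.sum(axis=1)
        probs = np.empty(k, dtype=np.float64)

        ndt_sum = np.zeros((D, k), dtype=np.float64)
        ntw_sum = np.zeros((k, V), dtype=np.float64)
        n_saved = 0
        trace = np.empty(self.n_iter, dtype=np.float64)
        for it in range(self.n_iter):
            uniforms = rng.random(n_tokens)
            _gibbs_sweep(doc_ids, word_ids, z, ndt, ntw, nt, alpha, beta,
                         uniforms, probs)
            trace[it] = joint_log_likelihood(ndt, ntw, alpha, beta)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                ndt_sum += ndt
                ntw_sum += ntw
                n_saved += 1

        ndt_bar = ndt_sum / n_saved
        ntw_bar = ntw_sum / n_saved
        self.components_ = (ntw_bar + beta) / (ntw_bar.sum(axis=1, keepdims=True) + V * beta)
        self.doc_topic_ = (ndt_bar + alpha) / (ndt_bar.sum(axis=1, keepdims=True) + k * alpha)
        self.assignments_ = z
        self.token_doc_ids_ = doc_ids
        self.token_word_ids_ = word_ids
        self.log_likelihood_trace_ = trace
        self.n_samples_saved_ = n_saved
        self.n_features_in_ = V
        return self

    def transform(self, X, n_iter=200, burn_in=100):
        """Infer θ for new documents by Gibbs fold-in with φ fixed."""
        check_is_fitted(self, "components_")
        X = sp.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("vocabulary size mismatch")
        k = self.n_topics
        alpha = self._effective_alpha()
        rng = np.random.default_rng(self.random_state)
        out = np.empty((X.shape[0], k))
        probs = np.empty(k, dtype=np.float64)
        for i in range(X.shape[0]):
            row = X.getrow(i)
            word_ids = np.repeat(row.indices.astype(np.int64),
                                 row.data.astype(np.int64))
            if word_ids.size == 0:
                warnings.warn("empty document: returning uniform topic distribution")
                out[i] = np.full(k, 1.0 / k)
                continue
            z = rng.integers(0, k, size=word_ids.size).astype(np.int64)
            ndt_row = np.bincount(z, minlength=k).astype(np.int64)
            acc = np.zeros(k)
            n_saved = 0
            for it in range(n_iter):
                uniforms = rng.random(word_ids.size)
                _fold_in_sweep(word_ids, z, ndt_row, self.components_, alpha,
                               uniforms, probs)
                if it >= burn_in:
                    acc += ndt_row
                    n_saved += 1
            theta = (acc / n_saved + alpha) / (word_ids.size + k * alpha)
            out[i] = theta / theta.sum()
        return out


# ---------------------------------------------------------------------------
# functional surface


def fit_lda(X, k, alpha=None, beta=0.01, n_iter=1500, burn_in=1000, thin=10,
            seed=None) -> GibbsLDA:
    return GibbsLDA(n_topics=k, alpha=alpha, beta=beta, n_iter=n_iter,
                    burn_in=burn_in, thin=thin, random_state=seed).fit(X)


def infer_topics(fit: GibbsLDA, counts, n_iter=200, burn_in=100):
    """θ vector for one held-out term-count vector over the fit's vocabulary."""
    counts = np.asarray(counts).reshape(1, -1)
    return fit.transform(sp.csr_matrix(counts), n_iter=n_iter, burn_in=burn_in)[0]


def top_words(fit: GibbsLDA, topic: int, n: int, vocab=None):
    """Top-n stems of a topic by φ (descending; ties broken lexicographically
    when a vocabulary is supplied, by column index otherwise)."""
    phi_t = fit.components_[topic]
    if not 1 <= n <= phi_t.shape[0]:
        raise ValueError("need 1 <= n <= V")
    if vocab is None:
        order = np.lexsort((np.arange(phi_t.shape[0]), -phi_t))
        return order[:n]
    names = np.asarray(list(vocab))
    order = np.lexsort((names, -phi_t))
    return list(names[order[:n]])


def topic_coherence(fit: GibbsLDA, X, top_n: int = 10, eps: float = 1e-12) -> pd.DataFrame:
    """Per-topic mean pairwise NPMI of the top_n words.

    Co-occurrence is boolean at the document level: p(a) is the fraction
    of documents containing stem a, p(ab) the fraction containing both.
    NPMI(a,b) = log(p(ab) / (p(a) p(b))) / (−log p(ab)) lies in [−1, 1];
    the ε guard keeps never-co-occurring pairs finite (close to −1).
    """
    X = sp.csr_matrix(X)
    D, V = X.shape
    if top_n > V:
        raise ValueError("top_n exceeds vocabulary size")
    presence = (X > 0).astype(np.float64)
    rows = []
    for t in range(fit.n_topics):
        idx = np.asarray(top_words(fit, t, top_n))
        sub = presence[:, idx]
        co = (sub.T @ sub).toarray() / D  # joint document frequencies
        p = co.diagonal()
        vals = []
        for a, b in itertools.combinations(range(len(idx)), 2):
            pab = co[a, b]
            if p[a] <= 0 or p[b] <= 0:
                vals.append(-1.0)
                continue
            npmi = np.log((pab + eps) / (p[a] * p[b])) / -np.log(pab + eps)
            vals.append(float(npmi))
        rows.append({"topic": t, "coherence": float(np.mean(vals)) if vals else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["top_n"] = top_n
    out.attrs["k"] = fit.n_topics
    return out


def select_k(X, k_grid, top_n=10, **fit_params):
    """Fit LDA across a grid of k and pick the argmax of mean NPMI
    coherence; ties break toward smaller k."""
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    rows = []
    for k in k_grid:
        fit = fit_lda(X, k=k, **fit_params)
        rep = topic_coherence(fit, X, top_n=min(top_n, X.shape[1]))
        rows.append({"k": k, "mean_coherence": float(rep["coherence"].mean())})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_coherence"].idxmax(), "k"]  # idxmax: first max → smallest k
    return int(best), table


def exact_assignment_posterior(X, k, alpha, beta):
    """Exact posterior over all k^N token-assignment configurations.

    Brute-force enumeration of the collapsed joint; tractable only for a
    handful of tokens.  Returns (configurations, probabilities).
    """
    X = sp.csr_matrix(X)
    doc_ids, word_ids = _tokens_from_matrix(X)
    n = doc_ids.shape[0]
    if k ** n > 2_000_000:
        raise ValueError("enumeration infeasible for this corpus size")
    D, V = X.shape
    configs = list(itertools.product(range(k), repeat=n))
    logps = np.empty(len(configs))
    for ci, cfg in enumerate(configs):
        z = np.asarray(cfg)
        ndt = np.zeros((D, k), dtype=np.int64)
        ntw = np.zeros((k, V), dtype=np.int64)
        np.add.at(ndt, (doc_ids, z), 1)
        np.add.at(ntw, (z, word_ids), 1)
        logps[ci] = joint_log_likelihood(ndt, ntw, alpha, beta)
    logps -= logps.max()
    p = np.exp(logps)
    return configs, p / p.sum()


def sample_assignment_frequencies(X, k, alpha, beta, n_samples, burn_in=500, seed=0):
    """Empirical distribution over assignment configurations from the
    Gibbs sampler, for comparison with `exact_assignment_posterior`."""
    X = sp.csr_matrix(X)
    D, V = X.shape
    doc_ids, word_ids = _tokens_from_matrix(X)
    n = doc_ids.shape[0]
    rng = np.random.default_rng(seed)
    z = rng.integers(0, k, size=n).astype(np.int64)
    ndt = np.zeros((D, k), dtype=np.int64)
    ntw = np.zeros((k, V), dtype=np.int64)
    np.add.at(ndt, (doc_ids, z), 1)
    np.add.at(ntw, (z, word_ids), 1)
    nt = ntw.sum(axis=1)
    probs = np.empty(k, dtype=np.float64)
    counts: dict[tuple, int] = {}
    for it in range(burn_in + n_samples):
        uniforms = rng.random(n)
        _gibbs_sweep(doc_ids, word_ids, z, ndt, ntw, nt, alpha, beta, uniforms, probs)
        if it >= burn_in:
            key = tuple(int(t) for t in z)
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    return {cfg: c / total for cfg, c in counts.items()}
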