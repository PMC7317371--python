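import numpy as np
import pytest
import scipy.sparse as sp

from fieldscape import lda
from fieldscape.lda import (
    GibbsLDA, exact_assignment_posterior, fit_lda, gibbs_conditional,
    infer_topics, sample_assignment_frequencies, select_k, top_words,
    topic_coherence,
)
from conftest import hellinger_match, restricted_phi_true


class TestGibbsConditional:
    def test_hand_computed_example(self):
        p = gibbs_conditional([2, 0], [3, 0], [10, 5], alpha=0.5, beta=0.1, V=3)
        # unnormalized (2.5*3.1/10.3, 0.5*0.1/5.3)
        assert p == pytest.approx([0.98762, 0.01238], abs=1e-4)

    def test_all_zero_counts_give_uniform(self):
        p = gibbs_conditional([0, 0, 0], [0, 0, 0], [0, 0, 0], 0.3, 0.05, 4)
        assert p == pytest.approx([1 / 3] * 3)

    def test_normalization_on_random_states(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 8)
            p = gibbs_conditional(rng.integers(0, 20, k), rng.integers(0, 9, k),
                                  rng.integers(10, 50, k), 0.5, 0.01, 30)
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gibbs_conditional([-1, 2], [0, 0], [3, 3], 0.5, 0.1, 3)


class TestFit:
    def test_single_topic_closed_form(self):
        X = sp.csr_matrix(np.array([[3, 1, 0], [0, 2, 2]]))
        fit = fit_lda(X, k=1, beta=0.01, n_iter=20, burn_in=5, thin=1, seed=0)
        assert np.allclose(fit.doc_topic_, 1.0)
        counts = np.array([3, 3, 2], dtype=float)
        expected = (counts + 0.01) / (counts.sum() + 3 * 0.01)
        assert fit.components_[0] == pytest.approx(expected, abs=1e-12)

    def test_estimates_are_normalized_distributions(self, small_planted):
        fit = small_planted["fit"]
        assert np.allclose(fit.components_.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(fit.doc_topic_.sum(axis=1), 1.0, atol=1e-12)
        assert fit.assignments_.min() >= 0
        assert fit.assignments_.max() < fit.n_topics

    def test_log_likelihood_trend_improves(self, small_planted):
        trace = small_planted["fit"].log_likelihood_trace_
        assert trace[-50:].mean() > trace[:10].mean()

    def test_deterministic_under_seed(self):
        X = sp.csr_matrix(np.array([[2, 1, 0], [0, 1, 3], [1, 1, 1]]))
        f1 = fit_lda(X, k=2, n_iter=50, burn_in=10, seed=7)
        f2 = fit_lda(X, k=2, n_iter=50, burn_in=10, seed=7)
        assert np.array_equal(f1.components_, f2.components_)
        assert np.array_equal(f1.assignments_, f2.assignments_)

    def test_invalid_inputs(self):
        X = sp.csr_matrix(np.array([[1, 1]]))
        with pytest.raises(ValueError):
            fit_lda(X, k=2, n_iter=10, burn_in=20, seed=0)
        with pytest.raises(ValueError):
            fit_lda(sp.csr_matrix((2, 3)), k=2, n_iter=10, burn_in=1, seed=0)

    def test_sklearn_estimator_protocol(self):
        est = GibbsLDA(n_topics=4, n_iter=30, burn_in=10, random_state=1)
        params = est.get_params()
        assert params["n_topics"] == 4
        clone = GibbsLDA(**params)
        assert clone.get_params() == params
        est.set_params(n_topics=2)
        X = sp.csr_matrix(np.array([[2, 1, 1], [1, 0, 3]]))
        est.fit(X)
        assert est.components_.shape == (2, 3)
        assert est.doc_topic_.shape == (2, 2)

    def test_planted_two_block_separation(self):
        # eco-words vs cons-words: each topic's top words come from one block
        rng = np.random.default_rng(21)
        V = 20
        docs = []
        for i in range(60):
            block = i % 2
            words = rng.integers(0, 10, size=60) + 10 * block
            row = np.bincount(words, minlength=V)
            docs.append(row)
        X = sp.csr_matrix(np.array(docs))
        fit = fit_lda(X, k=2, n_iter=300, burn_in=100, seed=22)
        for t in range(2):
            top = top_words(fit, t, 10)
            frac_a = np.mean([w < 10 for w in top])
            assert max(frac_a, 1 - frac_a) >= 0.9


class TestExchangeability:
    def test_document_permutation_leaves_posterior_invariant(self):
        # both samplers approximate the same exact posterior, so their
        # averaged topic-word estimates agree up to topic relabeling
        X = sp.csr_matrix(np.array([[1, 1, 0], [0, 1, 1]]))
        Xp = X[::-1]
        fa = fit_lda(X, k=2, alpha=0.5, beta=0.1, n_iter=4000, burn_in=500,
                     thin=1, seed=3)
        fb = fit_lda(Xp, k=2, alpha=0.5, beta=0.1, n_iter=4000, burn_in=500,
                     thin=1, seed=4)
        dist, _ = hellinger_match(fa.components_, fb.components_)
        assert dist < 0.05


class TestEnumerationOracle:
    def test_sampler_matches_exact_posterior_tv(self):
        # compact version of the toy-corpus check (the full 50k-sample
        # run lives in the acceptance suite)
        X = sp.csr_matrix(np.array([[1, 1, 0], [0, 1, 1]]))
        configs, probs = exact_assignment_posterior(X, k=2, alpha=0.5, beta=0.1)
        freq = sample_assignment_frequencies(X, k=2, alpha=0.5, beta=0.1,
                                             n_samples=8000, seed=11)
        exact = dict(zip(configs, probs))
        tv = 0.5 * sum(abs(exact.get(c, 0.0) - f) for c, f in freq.items())
        tv += 0.5 * sum(p for c, p in exact.items() if c not in freq)
        assert tv < 0.08

    def test_enumeration_guard(self):
        X = sp.csr_matrix(np.ones((10, 10), dtype=int) * 3)
        with pytest.raises(ValueError, match="infeasible"):
            exact_assignment_posterior(X, k=10, alpha=0.1, beta=0.1)


class TestInferTopics:
    def test_exclusive_words_pin_the_topic(self, small_planted):
        truth, vocab, fit = (small_planted[k] for k in ("truth", "vocab", "fit"))
        phi_true = restricted_phi_true(truth, vocab)
        _, fit_of_true = hellinger_match(fit.components_, phi_true)
        # build a document from the 10 words most exclusive to planted topic 0
        ratio = phi_true[0] / (phi_true.sum(axis=0) + 1e-300)
        top = np.argsort(-ratio)[:10]
        counts = np.zeros(len(vocab.stems))
        counts[top] = 30
        theta = infer_topics(fit, counts, n_iter=300, burn_in=100)
        assert theta[fit_of_true[0]] > 0.9

    def test_training_document_self_consistency(self, small_planted):
        fit, X = small_planted["fit"], small_planted["X"]
        row = np.asarray(X[0].todense()).ravel()
        theta = infer_topics(fit, row, n_iter=400, burn_in=200)
        assert np.abs(theta - fit.doc_topic_[0]).sum() < 0.1

    def test_empty_document_uniform(self, small_planted):
        fit = small_planted["fit"]
        with pytest.warns(UserWarning, match="empty document"):
            theta = infer_topics(fit, np.zeros(fit.n_features_in_))
        assert theta == pytest.approx(np.full(fit.n_topics, 1 / fit.n_topics))


class TestTopWords:
    def test_full_ranking_is_a_permutation(self, small_planted):
        fit, vocab = small_planted["fit"], small_planted["vocab"]
        ranked = top_words(fit, 0, len(vocab), vocab.stems)
        assert sorted(ranked) == sorted(vocab.stems)

    def test_single_topic_ranking_equals_frequency_ranking(self):
        X = sp.csr_matrix(np.array([[5, 3, 7, 1]]))
        fit = fit_lda(X, k=1, n_iter=20, burn_in=5, seed=0)
        assert list(top_words(fit, 0, 4)) == [2, 0, 1, 3]

    def test_ties_break_lexicographically(self):
        X = sp.csr_matrix(np.array([[2, 2, 2]]))
        fit = fit_lda(X, k=1, n_iter=20, burn_in=5, seed=0)
        assert top_words(fit, 0, 3, ["cc", "aa", "bb"]) == ["aa", "bb", "cc"]

    def test_bounds_checked(self, small_planted):
        with pytest.raises(ValueError):
            top_words(small_planted["fit"], 0, 0)


class TestCoherence:
    def _fit_for(self, X, top_n):
        fit = fit_lda(sp.csr_matrix(X), k=1, n_iter=10, burn_in=2, seed=0)
        return topic_coherence(fit, sp.csr_matrix(X), top_n=top_n)

    def test_perfect_cooccurrence_gives_one(self):
        # two words in 5 of 10 docs, always together: NPMI = 1
        X = np.zeros((10, 2), dtype=int)
        X[:5] = 1
        rep = self._fit_for(X, top_n=2)
        assert rep["coherence"][0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_words_give_zero(self):
        # word a in docs 0..4, word b in docs 0,1,5,6 over D=10:
        # p(ab)=0.2 = p(a)p(b) exactly
        X = np.zeros((10, 2), dtype=int)
        X[:5, 0] = 1
        X[[0, 1, 5, 6], 1] = 1
        rep = self._fit_for(X, top_n=2)
        assert rep["coherence"][0] == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_words_approach_minus_one(self):
        X = np.zeros((10, 2), dtype=int)
        X[:5, 0] = 1
        X[5:, 1] = 1
        rep = self._fit_for(X, top_n=2)
        assert rep["coherence"][0] < -0.9

    def test_top_n_validated(self, small_planted):
        with pytest.raises(ValueError):
            topic_coherence(small_planted["fit"], small_planted["X"],
                            top_n=10_000)

    def test_planted_topics_beat_random_word_sets(self, small_planted):
        fit, X = small_planted["fit"], small_planted["X"]
        rep = topic_coherence(fit, X, top_n=10)
        rng = np.random.default_rng(5)
        random_scores = []
        presence = (X > 0).astype(float)
        D = X.shape[0]
        for _ in range(20):
            idx = rng.choice(X.shape[1], size=10, replace=False)
            co = (presence[:, idx].T @ presence[:, idx]).toarray() / D
            p = co.diagonal()
            vals = []
            for a in range(10):
                for b in range(a + 1, 10):
                    pab = co[a, b]
                    vals.append(np.log((pab + 1e-12) / (p[a] * p[b]))
                                / -np.log(pab + 1e-12))
            random_scores.append(np.mean(vals))
        assert rep["coherence"].mean() > np.mean(random_scores)


class TestSelectK:
    def test_single_value_grid(self, small_planted):
        k, table = select_k(small_planted["X"], [3], n_iter=60, burn_in=20,
                            seed=0)
        assert k == 3 and len(table) == 1

    def test_tie_breaks_toward_smaller_k(self, monkeypatch):
        # force identical coherence at every k
        monkeypatch.setattr(
            lda, "topic_coherence",
            lambda fit, X, top_n=10: __import__("pandas").DataFrame(
                {"topic": range(fit.n_topics), "coherence": 0.5}))
        X = sp.csr_matrix(np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]))
        k, table = select_k(X, [3, 2], n_iter=20, burn_in=5, seed=0)
        assert k == 2  # grid is sorted; first (smallest) argmax wins

    def test_empty_grid_rejected(self, small_planted):
        with pytest.raises(ValueError):
            select_k(small_planted["X"], [])

    def test_planted_k_scores_above_extremes(self, small_planted):
        X = small_planted["X"]  # planted k = 3
        k_star, table = select_k(X, [2, 3, 12], n_iter=150, burn_in=50, seed=1)
        scores = dict(zip(table["k"], table["mean_coherence"]))
        assert scores[3] >= scores[12]
        assert k_star in (2, 3)
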