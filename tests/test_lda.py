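"""Gibbs sampler correctness: exact oracles, invariants, recovery."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import hcstopics as ht
from hcstopics.lda import (
    collapsed_log_likelihood,
    expand_tokens,
    match_rows,
    n_retained_samples,
)
from conftest import TEST_LDA, planted_group_sets, recovered_partition


# ---------------------------------------------------------------------------
# independent exhaustive oracle (lgamma arithmetic, no package internals)
# ---------------------------------------------------------------------------

def enumerate_posterior(token_doc, token_word, D, V, K, alpha, beta):
    """Exact posterior over all K^N assignments of a tiny corpus.

    Returns (log normalizing constant, per-token marginals p(z_i = k),
    co-assignment matrix p(z_i == z_j)).
    """
    N = len(token_doc)
    logws = []
    states = list(itertools.product(range(K), repeat=N))
    for zs in states:
        n_dk = np.zeros((D, K))
        n_kw = np.zeros((K, V))
        for i, k in enumerate(zs):
            n_dk[token_doc[i], k] += 1
            n_kw[k, token_word[i]] += 1
        lw = 0.0
        for d in range(D):
            lw += math.lgamma(K * alpha) - K * math.lgamma(alpha)
            for k in range(K):
                lw += math.lgamma(n_dk[d, k] + alpha)
            lw -= math.lgamma(n_dk[d].sum() + K * alpha)
        for k in range(K):
            lw += math.lgamma(V * beta) - V * math.lgamma(beta)
            for w in range(V):
                lw += math.lgamma(n_kw[k, w] + beta)
            lw -= math.lgamma(n_kw[k].sum() + V * beta)
        logws.append(lw)
    logws = np.array(logws)
    m = logws.max()
    w = np.exp(logws - m)
    total = w.sum()
    marg = np.zeros((N, K))
    coassign = np.zeros((N, N))
    for weight, zs in zip(w, states):
        for i, k in enumerate(zs):
            marg[i, k] += weight
            for j, kj in enumerate(zs):
                if k == kj:
                    coassign[i, j] += weight
    return m + math.log(total), marg / total, coassign / total


class TestSmallScaleOracle:
    def test_collapsed_loglik_matches_enumeration_term(self, tiny_corpus):
        """Our closed-form log p(w,z) agrees with independent lgamma sums."""
        cfg = ht.LDAConfig(n_topics=2, alpha=0.5, beta=0.5,
                           n_iterations=10, burn_in=0, sample_lag=1, seed=0)
        model = ht.fit_lda(tiny_corpus, cfg)
        ll = ht.log_likelihood(model, tiny_corpus)
        # recompute with the oracle's arithmetic for the model's final z
        token_doc, token_word = model.token_doc, model.token_word
        n_dk = np.zeros((2, 2))
        n_kw = np.zeros((2, 2))
        for i, k in enumerate(model.z):
            n_dk[token_doc[i], k] += 1
            n_kw[k, token_word[i]] += 1
        expected = 0.0
        for d in range(2):
            expected += math.lgamma(2 * 0.5) - 2 * math.lgamma(0.5)
            expected += sum(math.lgamma(n_dk[d, k] + 0.5) for k in range(2))
            expected -= math.lgamma(n_dk[d].sum() + 2 * 0.5)
        for k in range(2):
            expected += math.lgamma(2 * 0.5) - 2 * math.lgamma(0.5)
            expected += sum(math.lgamma(n_kw[k, w] + 0.5) for w in range(2))
            expected -= math.lgamma(n_kw[k].sum() + 2 * 0.5)
        assert ll == pytest.approx(expected)

    def test_gibbs_matches_enumeration_on_three_tokens(self):
        """Posterior marginals and co-assignments vs brute force, K=2."""
        corpus = ht.Corpus(
            doc_ids=("a@1", "b@1"), doc_drugs=("a", "b"), doc_times=(1.0, 1.0),
            term_ids=("u", "v"), counts=np.array([[1, 1], [1, 0]], dtype=np.int64),
        )
        cfg = ht.LDAConfig(n_topics=2, alpha=0.7, beta=0.4,
                           n_iterations=20_500, burn_in=500, sample_lag=2, seed=11)
        model = ht.fit_lda(corpus, cfg, store_samples=True)
        token_doc, token_word = expand_tokens(corpus)
        _, marg, coassign = enumerate_posterior(token_doc, token_word, 2, 2, 2, 0.7, 0.4)
        np.testing.assert_allclose(model.z_marginals, marg, atol=0.02)
        s = model.z_samples
        gibbs_co = (s[:, :, None] == s[:, None, :]).mean(axis=0)
        np.testing.assert_allclose(gibbs_co, coassign, atol=0.02)

    def test_log_evidence_is_reproduced_by_sampler_states(self, tiny_corpus):
        """Every sampled state's weight is bounded by the enumeration's
        normalizing constant (log-sum-exp over all states)."""
        token_doc, token_word = expand_tokens(tiny_corpus)
        log_z, _, _ = enumerate_posterior(token_doc, token_word, 2, 2, 2, 0.5, 0.1)
        cfg = ht.LDAConfig(n_topics=2, alpha=0.5, beta=0.1,
                           n_iterations=200, burn_in=50, sample_lag=1, seed=3)
        model = ht.fit_lda(tiny_corpus, cfg)
        assert ht.log_likelihood(model, tiny_corpus) < log_z
        assert np.all(model.log_likelihood_trace < log_z)


class TestSamplerInvariants:
    def test_cpt_rows_normalized_and_positive(self, planted_model):
        np.testing.assert_allclose(planted_model.doc_topic.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(planted_model.topic_word.sum(axis=1), 1.0, atol=1e-9)
        assert planted_model.doc_topic.min() > 0
        assert planted_model.topic_word.min() > 0

    def test_final_state_counts_conserved(self, planted_run):
        _, corpus, model = planted_run
        K = model.n_topics
        n_dk = np.zeros((corpus.n_docs, K), dtype=np.int64)
        np.add.at(n_dk, (model.token_doc, model.z), 1)
        np.testing.assert_array_equal(n_dk.sum(axis=1), corpus.counts.sum(axis=1))
        n_kw = np.zeros((K, corpus.n_terms), dtype=np.int64)
        np.add.at(n_kw, (model.z, model.token_word), 1)
        np.testing.assert_array_equal(n_kw.sum(axis=1), n_dk.sum(axis=0))

    def test_same_seed_reproduces_model(self, tiny_corpus):
        cfg = ht.LDAConfig(n_topics=2, n_iterations=50, burn_in=10, sample_lag=2, seed=9)
        a = ht.fit_lda(tiny_corpus, cfg)
        b = ht.fit_lda(tiny_corpus, cfg)
        np.testing.assert_array_equal(a.doc_topic, b.doc_topic)
        np.testing.assert_array_equal(a.topic_word, b.topic_word)
        np.testing.assert_array_equal(a.z, b.z)

    def test_trace_rises_from_random_start(self, planted_model):
        trace = planted_model.log_likelihood_trace
        assert np.all(np.isfinite(trace))
        assert trace[-100:].mean() > trace[0]

    def test_empty_document_rejected(self):
        corpus = ht.Corpus(
            doc_ids=("a@1", "b@1"), doc_drugs=("a", "b"), doc_times=(1.0, 1.0),
            term_ids=("u",), counts=np.array([[1], [0]], dtype=np.int64),
        )
        with pytest.raises(ht.DataError, match="no tokens"):
            ht.fit_lda(corpus, ht.LDAConfig(n_topics=2, n_iterations=10,
                                            burn_in=0, sample_lag=1, seed=0))

    def test_vocabulary_mismatch_is_alignment_error(self, tiny_corpus):
        cfg = ht.LDAConfig(n_topics=2, n_iterations=10, burn_in=0, sample_lag=1, seed=0)
        model = ht.fit_lda(tiny_corpus, cfg)
        import dataclasses
        other = dataclasses.replace(tiny_corpus, term_ids=("x", "y"))
        with pytest.raises(ht.AlignmentError):
            ht.log_likelihood(model, other)


class TestSeparableLimit:
    def test_one_term_per_document_concentrates_topics(self):
        # K = V = 3, each document repeats a single distinct term
        counts = np.diag([20, 20, 20]).astype(np.int64)
        corpus = ht.Corpus(
            doc_ids=("a@1", "b@1", "c@1"), doc_drugs=("a", "b", "c"),
            doc_times=(1.0,) * 3, term_ids=("u", "v", "w"), counts=counts,
        )
        cfg = ht.LDAConfig(n_topics=3, alpha=0.1, beta=0.01,
                           n_iterations=500, burn_in=200, sample_lag=5, seed=4)
        model = ht.fit_lda(corpus, cfg)
        perm = match_rows(np.eye(3), model.topic_word)
        for k in range(3):
            assert model.topic_word[perm[k], k] > 0.95


class TestRankTerms:
    def _model(self, phi):
        phi = np.asarray(phi, dtype=float)
        return ht.TopicModel(
            config=ht.LDAConfig(n_topics=phi.shape[0]),
            term_ids=tuple("abc"[: phi.shape[1]]),
            doc_ids=("d@1",), z=np.zeros(1, dtype=np.int64),
            doc_topic=np.full((1, phi.shape[0]), 1 / phi.shape[0]),
            topic_word=phi, log_likelihood_trace=np.zeros(1),
            token_doc=np.zeros(1, dtype=np.int64),
            token_word=np.zeros(1, dtype=np.int64),
            z_marginals=np.full((1, phi.shape[0]), 1 / phi.shape[0]),
        )

    def test_sorts_by_descending_probability(self):
        model = self._model([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
        assert [t for t, _ in ht.rank_terms(model, 1)] == ["a", "b", "c"]
        assert [t for t, _ in ht.rank_terms(model, 2)] == ["c", "b", "a"]

    def test_uniform_topic_preserves_catalog_order(self):
        model = self._model([[1 / 3] * 3, [1 / 3] * 3])
        assert [t for t, _ in ht.rank_terms(model, 1)] == ["a", "b", "c"]

    def test_bad_index_raises(self):
        model = self._model([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(IndexError):
            ht.rank_terms(model, 3)

    def test_match_topics_identity_and_swap(self):
        phi = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        model = self._model(phi)
        assert ht.match_topics(model, model) == {1: 1, 2: 2}
        swapped = self._model(phi[::-1])
        assert ht.match_topics(model, swapped) == {1: 2, 2: 1}


class TestRecovery:
    def test_planted_corpus_recovers_event_groups(self, planted_run):
        dataset, _, model = planted_run
        assert recovered_partition(model) is not None
        planted = set(map(frozenset, planted_group_sets(dataset).values()))
        recovered = set(map(frozenset, recovered_partition(model).values()))
        assert recovered == planted

    def test_two_seeds_give_stable_matched_topics(self, planted_run):
        dataset, corpus, model_a = planted_run
        model_b = ht.fit_lda(corpus, ht.LDAConfig(**TEST_LDA, seed=999))
        perm = ht.match_topics(model_a, model_b)
        for ka, kb in perm.items():
            a = model_a.topic_word[ka - 1]
            b = model_b.topic_word[kb - 1]
            cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos >= 0.95

    def test_sklearn_variational_lda_agrees_on_partition(self, planted_run):
        """Independent cross-check: a variational LDA implementation finds
        the same disjoint endpoint partition on the planted corpus."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        dataset, corpus, _ = planted_run
        vb = sklearn.LatentDirichletAllocation(
            n_components=3, random_state=0, max_iter=50
        ).fit(corpus.counts)
        phi = vb.components_ / vb.components_.sum(axis=1, keepdims=True)
        partition: dict[int, set[str]] = {}
        for j, term in enumerate(corpus.term_ids):
            partition.setdefault(int(np.argmax(phi[:, j])), set()).add(term)
        planted = set(map(frozenset, planted_group_sets(dataset).values()))
        assert set(map(frozenset, partition.values())) == planted


def test_retained_sample_count_formula():
    cfg = ht.LDAConfig(n_iterations=100, burn_in=40, sample_lag=7, seed=0)
    sweeps = [s for s in range(100) if s >= 40 and (s - 40) % 7 == 0]
    assert n_retained_samples(cfg) == len(sweeps)
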