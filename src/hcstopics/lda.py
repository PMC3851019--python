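"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The corpus model: each document d draws a topic mixture theta_d from a
symmetric Dirichlet(alpha); each token draws a topic z ~ Mult(theta_d)
and then a word from that topic's distribution phi_z, itself drawn from
a symmetric Dirichlet(beta). Collapsing theta and phi analytically
leaves a Gibbs chain over the token-level topic assignments z with the
familiar full conditional

    p(z_i = k | z_-i, w)  ∝  (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

The two conditional probability tables the downstream diagnostics need,
p(topic|document) and p(word|topic), are posterior means over retained
post-burn-in samples with per-sample Dirichlet smoothing

    theta_dk = (n_dk + alpha) / (n_d + K*alpha)
    phi_kw   = (n_kw + beta)  / (n_k + V*beta)

Runs are reproducible: documents are processed in fixed order, tokens in
term-catalog order, and all randomness flows from the config seed. The
joint log probability log p(w, z | alpha, beta) is traced every sweep as
a convergence monitor. Token-level marginal posteriors p(z_i = k) are
accumulated over the same retained samples; they are the quantity that
small corpora allow to be checked against exhaustive enumeration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .errors import AlignmentError, ConfigurationError, DataError
from .preprocess import Corpus


@dataclass(frozen=True)
class LDAConfig:
    """Sampler settings.

    alpha defaults to 50/K and beta to 0.1 (the common convention for
    small-vocabulary corpora); both are overridable. ``n_iterations``
    counts total Gibbs sweeps, of which the first ``burn_in`` are
    discarded; every ``sample_lag``-th sweep thereafter contributes to
    the posterior-mean CPT estimates. The seed is mandatory — there is
    no silent clock seeding.
    """

    n_topics: int = 3
    alpha: float | None = None
    beta: float = 0.1
    n_iterations: int = 2000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ConfigurationError("n_topics must be >= 2")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ConfigurationError("need 0 <= burn_in < n_iterations")
        if self.sample_lag < 1:
            raise ConfigurationError("sample_lag must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.n_topics


@dataclass(frozen=True)
class TopicModel:
    """Fitted LDA state and posterior-mean CPTs."""

    config: LDAConfig
    term_ids: tuple[str, ...]
    doc_ids: tuple[str, ...]
    z: np.ndarray                    # final-state topic per token
    doc_topic: np.ndarray            # (n_docs, K) p(topic|document)
    topic_word: np.ndarray           # (K, V) p(word|topic)
    log_likelihood_trace: np.ndarray # per-sweep log p(w, z | alpha, beta)
    token_doc: np.ndarray            # token -> document index
    token_word: np.ndarray           # token -> term index
    z_marginals: np.ndarray          # (n_tokens, K) posterior p(z_i = k)
    z_samples: np.ndarray | None = None  # retained z snapshots, if stored

    @property
    def n_topics(self) -> int:
        return self.config.n_topics


def expand_tokens(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    """Unroll the count matrix into parallel (doc, word) token arrays.

    Documents in corpus order, tokens within a document in term-catalog
    order; this fixed order is what makes runs reproducible.
    """
    docs, words = [], []
    for d in range(corpus.n_docs):
        for w in range(corpus.n_terms):
            c = int(corpus.counts[d, w])
            if c:
                docs.extend([d] * c)
                words.extend([w] * c)
    return np.asarray(docs, dtype=np.int64), np.asarray(words, dtype=np.int64)


@njit(cache=True)
def _gibbs(token_doc, token_word, z, K, V, D, alpha, beta,
           n_iterations, burn_in, sample_lag, seed, samples):
    np.random.seed(seed)
    N = token_doc.shape[0]
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    n_d = np.zeros(D, dtype=np.int64)
    for i in range(N):
        d, w, k = token_doc[i], token_word[i], z[i]
        n_dk[d, k] += 1
        n_kw[k, w] += 1
        n_k[k] += 1
        n_d[d] += 1

    theta_sum = np.zeros((D, K))
    phi_sum = np.zeros((K, V))
    zmarg = np.zeros((N, K))
    trace = np.empty(n_iterations)
    n_samples = 0
    probs = np.empty(K)

    # constant part of log p(w, z | alpha, beta)
    base = D * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) \
        + K * (math.lgamma(V * beta) - V * math.lgamma(beta))

    for sweep in range(n_iterations):
        for i in range(N):
            d, w, k = token_doc[i], token_word[i], z[i]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                p = (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + V * beta)
                probs[kk] = p
                total += p
            u = np.random.random() * total
            acc = 0.0
            knew = K - 1
            for kk in range(K):
                acc += probs[kk]
                if u < acc:
                    knew = kk
                    break
            z[i] = knew
            n_dk[d, knew] += 1
            n_kw[knew, w] += 1
            n_k[knew] += 1

        ll = base
        for d in range(D):
            for kk in range(K):
                ll += math.lgamma(n_dk[d, kk] + alpha)
            ll -= math.lgamma(n_d[d] + K * alpha)
        for kk in range(K):
            for w in range(V):
                ll += math.lgamma(n_kw[kk, w] + beta)
            ll -= math.lgamma(n_k[kk] + V * beta)
        trace[sweep] = ll

        if sweep >= burn_in and (sweep - burn_in) % sample_lag == 0:
            if samples.shape[0] > 0:
                for i in range(N):
                    samples[n_samples, i] = z[i]
            n_samples += 1
            for d in range(D):
                denom = n_d[d] + K * alpha
                for kk in range(K):
                    theta_sum[d, kk] += (n_dk[d, kk] + alpha) / denom
            for kk in range(K):
                denom = n_k[kk] + V * beta
                for w in range(V):
                    phi_sum[kk, w] += (n_kw[kk, w] + beta) / denom
            for i in range(N):
                zmarg[i, z[i]] += 1.0

    return theta_sum, phi_sum, zmarg, trace, n_samples


def n_retained_samples(config: LDAConfig) -> int:
    """Number of post-burn-in sweeps that contribute to the CPT estimates."""
    return (config.n_iterations - config.burn_in + config.sample_lag - 1) // config.sample_lag


def fit_lda(
    corpus: Corpus, config: LDAConfig, store_samples: bool = False
) -> TopicModel:
    """Fit LDA to a corpus by collapsed Gibbs sampling.

    Raises a data error on an empty corpus or any empty document; the
    same corpus, config and seed always return the identical model.
    With ``store_samples=True`` every retained z snapshot is kept on the
    model (meant for small corpora, where posterior quantities beyond
    the CPT means — e.g. token co-assignment probabilities — are wanted).
    """
    if corpus.n_docs == 0 or corpus.n_terms == 0:
        raise DataError("corpus is empty")
    doc_totals = corpus.counts.sum(axis=1)
    if np.any(doc_totals < 1):
        empty = [corpus.doc_ids[i] for i in np.flatnonzero(doc_totals < 1)[:5]]
        raise DataError(f"documents with no tokens: {empty}")

    token_doc, token_word = expand_tokens(corpus)
    K, V, D = config.n_topics, corpus.n_terms, corpus.n_docs
    alpha, beta = config.effective_alpha, config.beta

    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, K, size=token_doc.shape[0]).astype(np.int64)
    # numba's np.random.seed takes a uint32; derive one from the config seed
    inner_seed = int(rng.integers(0, 2**31 - 1))

    n_keep = n_retained_samples(config) if store_samples else 0
    samples = np.zeros((n_keep, token_doc.shape[0]), dtype=np.int8)
    theta_sum, phi_sum, zmarg, trace, n_samples = _gibbs(
        token_doc, token_word, z, K, V, D, alpha, beta,
        config.n_iterations, config.burn_in, config.sample_lag, inner_seed,
        samples,
    )
    if n_samples == 0:  # unreachable given burn_in < n_iterations
        raise ConfigurationError("no retained samples")

    return TopicModel(
        config=config,
        term_ids=tuple(corpus.term_ids),
        doc_ids=tuple(corpus.doc_ids),
        z=z,
        doc_topic=theta_sum / n_samples,
        topic_word=phi_sum / n_samples,
        log_likelihood_trace=trace,
        token_doc=token_doc,
        token_word=token_word,
        z_marginals=zmarg / n_samples,
        z_samples=samples if store_samples else None,
    )


def collapsed_log_likelihood(
    n_dk: np.ndarray, n_kw: np.ndarray, alpha: float, beta: float
) -> float:
    """log p(w, z | alpha, beta) from the sufficient count statistics."""
    D, K = n_dk.shape
    _, V = n_kw.shape
    n_d = n_dk.sum(axis=1)
    n_k = n_kw.sum(axis=1)
    ll = D * (gammaln(K * alpha) - K * gammaln(alpha))
    ll += K * (gammaln(V * beta) - V * gammaln(beta))
    ll += gammaln(n_dk + alpha).sum() - gammaln(n_d + K * alpha).sum()
    ll += gammaln(n_kw + beta).sum() - gammaln(n_k + V * beta).sum()
    return float(ll)


def log_likelihood(model: TopicModel, corpus: Corpus) -> float:
    """Joint log p(w, z | alpha, beta) of the model's final assignment state."""
    if tuple(corpus.term_ids) != model.term_ids:
        raise AlignmentError("model and corpus vocabularies differ")
    K = model.n_topics
    D, V = corpus.n_docs, corpus.n_terms
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_dk, (model.token_doc, model.z), 1)
    np.add.at(n_kw, (model.z, model.token_word), 1)
    return collapsed_log_likelihood(
        n_dk, n_kw, model.config.effective_alpha, model.config.beta
    )


def rank_terms(model: TopicModel, topic: int) -> list[tuple[str, float]]:
    """Vocabulary of one topic (1-based index) sorted by descending
    p(word|topic); ties keep catalog order."""
    if not 1 <= topic <= model.n_topics:
        raise IndexError(f"topic must be in 1..{model.n_topics}, got {topic}")
    row = model.topic_word[topic - 1]
    order = np.argsort(-row, kind="stable")
    return [(model.term_ids[i], float(row[i])) for i in order]


def match_topics(model_a: TopicModel, model_b: TopicModel) -> dict[int, int]:
    """Optimal topic alignment between two fits of the same corpus family.

    Topic labels are exchangeable across runs; this finds the permutation
    maximizing summed cosine similarity between matched p(word|topic)
    rows (Hungarian assignment). Returns {topic_a: topic_b}, 1-based.
    """
    if model_a.term_ids != model_b.term_ids:
        raise AlignmentError("vocabularies differ")
    if model_a.n_topics != model_b.n_topics:
        raise AlignmentError("topic counts differ")
    sim = cosine_similarity_matrix(model_a.topic_word, model_b.topic_word)
    rows, cols = linear_sum_assignment(-sim)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of a and rows of b."""
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    return an @ bn.T


def match_rows(reference: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Hungarian row matching of an estimated CPT to a reference CPT.

    Returns ``perm`` such that ``estimate[perm[k]]`` corresponds to
    ``reference[k]`` (0-based)."""
    sim = cosine_similarity_matrix(reference, estimate)
    _, cols = linear_sum_assignment(-sim)
    return cols


# ---------------------------------------------------------------------------
# generative sampling (for simulation-based checks of the sampler)
# ---------------------------------------------------------------------------

def sample_lda_corpus(
    n_docs: int,
    doc_length: int,
    topic_word: np.ndarray,
    alpha: float,
    seed: int,
    term_ids: Sequence[str] | None = None,
) -> tuple[Corpus, np.ndarray]:
    """Draw a corpus exactly from the LDA generative process.

    Returns the corpus and the true document-topic mixtures theta.
    """
    topic_word = np.asarray(topic_word, dtype=float)
    K, V = topic_word.shape
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet(np.full(K, alpha), size=n_docs)
    counts = np.zeros((n_docs, V), dtype=np.int64)
    for d in range(n_docs):
        zs = rng.choice(K, size=doc_length, p=theta[d])
        for k in range(K):
            nk = int((zs == k).sum())
            if nk:
                counts[d] += rng.multinomial(nk, topic_word[k])
    if term_ids is None:
        term_ids = tuple(f"term_{j + 1}" for j in range(V))
    corpus = Corpus(
        doc_ids=tuple(f"doc_{d + 1}@0" for d in range(n_docs)),
        doc_drugs=tuple(f"doc_{d + 1}" for d in range(n_docs)),
        doc_times=tuple(0.0 for _ in range(n_docs)),
        term_ids=tuple(term_ids),
        counts=counts,
    )
    return corpus, theta


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_doc_topic(model: TopicModel, path: str | Path) -> None:
    df = pd.DataFrame(
        model.doc_topic, columns=[f"topic_{k + 1}" for k in range(model.n_topics)]
    )
    df.insert(0, "doc_id", list(model.doc_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_topic_word(model: TopicModel, path: str | Path) -> None:
    df = pd.DataFrame(
        model.topic_word.T, columns=[f"topic_{k + 1}" for k in range(model.n_topics)]
    )
    df.insert(0, "term_id", list(model.term_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_loglik_trace(model: TopicModel, path: str | Path) -> None:
    pd.DataFrame(
        {"sweep": np.arange(1, len(model.log_likelihood_trace) + 1),
         "log_likelihood": model.log_likelihood_trace}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_model_json(model: TopicModel, path: str | Path) -> None:
    from . import __version__

    meta = {
        "software_version": __version__,
        "config": {
            "n_topics": model.config.n_topics,
            "alpha": model.config.effective_alpha,
            "beta": model.config.beta,
            "n_iterations": model.config.n_iterations,
            "burn_in": model.config.burn_in,
            "sample_lag": model.config.sample_lag,
            "seed": model.config.seed,
        },
        "vocabulary": list(model.term_ids),
        "documents": list(model.doc_ids),
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def read_doc_topic(path: str | Path) -> pd.DataFrame:
    """doc_topic.tsv as a DataFrame indexed by doc_id."""
    return pd.read_csv(path, sep="\t", index_col="doc_id")


def read_topic_word(path: str | Path) -> pd.DataFrame:
    """topic_word.tsv as a DataFrame indexed by term_id."""
    return pd.read_csv(path, sep="\t", index_col="term_id")
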