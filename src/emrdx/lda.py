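"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Documents (records with sections concatenated) are modelled as mixtures
of K latent topics; the per-document topic proportions serve as the
feature vector handed to the multilabel classifiers.  Inference is
collapsed Gibbs sampling: topic assignments z are resampled token by
token from

    p(z = k | rest)  ∝  (C_dk + α) · (C_wk + β) / (C_·k + V·β)

with the current token excluded from the counts.  Point estimates use
the standard smoothed ratios: the document-topic distribution
(C_dk + α)/(n_d + K·α) and the topic-word distribution
(C_wk + β)/(C_·k + V·β).

The per-token sampling loop is compiled with numba; all randomness comes
from a single seeded generator, so fits are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .records import EMRecord


@njit(cache=False)
def _gibbs_sweep(doc_ids, word_ids, z, C_dk, C_wk, C_k, alpha, beta, u):
    V, K = C_wk.shape
    probs = np.empty(K)
    for t in range(z.shape[0]):
        d = doc_ids[t]
        w = word_ids[t]
        k = z[t]
        C_dk[d, k] -= 1
        C_wk[w, k] -= 1
        C_k[k] -= 1
        total = 0.0
        for kk in range(K):
            p = (C_dk[d, kk] + alpha) * (C_wk[w, kk] + beta) / (C_k[kk] + V * beta)
            probs[kk] = p
            total += p
        r = u[t] * total
        acc = 0.0
        new_k = K - 1
        for kk in range(K):
            acc += probs[kk]
            if r < acc:
                new_k = kk
                break
        z[t] = new_k
        C_dk[d, new_k] += 1
        C_wk[w, new_k] += 1
        C_k[new_k] += 1


@njit(cache=False)
def _foldin_sweep(word_ids, z, c_k_local, C_wk, C_k, alpha, beta, u):
    # resample a held-out document against frozen training counts
    V, K = C_wk.shape
    probs = np.empty(K)
    for t in range(z.shape[0]):
        w = word_ids[t]
        k = z[t]
        c_k_local[k] -= 1
        total = 0.0
        for kk in range(K):
            p = (c_k_local[kk] + alpha) * (C_wk[w, kk] + beta) / (C_k[kk] + V * beta)
            probs[kk] = p
            total += p
        r = u[t] * total
        acc = 0.0
        new_k = K - 1
        for kk in range(K):
            acc += probs[kk]
            if r < acc:
                new_k = kk
                break
        z[t] = new_k
        c_k_local[new_k] += 1


@dataclass
class TopicModel:
    """Fitted collapsed-Gibbs LDA state."""

    K: int
    alpha: float
    beta: float
    C_dk: np.ndarray  # D x K document-topic counts
    C_wk: np.ndarray  # V x K word-topic counts
    vocab: list[str]
    assignments: np.ndarray  # per-token topic labels (flattened corpus)
    doc_ids: np.ndarray
    word_ids: np.ndarray
    seed: int
    #: posterior-mean document-topic estimate averaged over the final
    #: sweeps (None when fitted with n_average=0)
    theta_mean: np.ndarray | None = None

    @property
    def n_docs(self) -> int:
        return self.C_dk.shape[0]

    @property
    def C_k(self) -> np.ndarray:
        return self.C_wk.sum(axis=0)

    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocab)}


def _as_docs(corpus) -> list[list[str]]:
    docs = []
    for item in corpus:
        docs.append(item.tokens() if isinstance(item, EMRecord) else list(item))
    return docs


def fit_lda(
    corpus,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iterations: int = 500,
    seed: int = 0,
    n_average: int = 0,
) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling.

    ``alpha`` defaults to 50/K.  ``corpus`` is a list of records or of
    token lists.  With ``n_average > 0`` the sampler runs that many
    additional sweeps and stores the posterior-mean document-topic
    estimate (averaging over samples reduces the variance of a
    single-state estimate); the count matrices always hold the final
    state.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha is None:
        alpha = 50.0 / K
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    docs = _as_docs(corpus)
    if not docs:
        raise ValueError("corpus must be non-empty")
    vocab = sorted({w for doc in docs for w in doc})
    if not vocab:
        raise ValueError("empty vocabulary: corpus has no tokens")
    widx = {w: i for i, w in enumerate(vocab)}

    doc_ids = np.concatenate(
        [np.full(len(doc), d, dtype=np.int64) for d, doc in enumerate(docs)]
    ) if any(docs) else np.empty(0, dtype=np.int64)
    word_ids = np.array([widx[w] for doc in docs for w in doc], dtype=np.int64)
    n_tokens = word_ids.shape[0]

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=n_tokens).astype(np.int64)

    D, V = len(docs), len(vocab)
    C_dk = np.zeros((D, K), dtype=np.int64)
    C_wk = np.zeros((V, K), dtype=np.int64)
    np.add.at(C_dk, (doc_ids, z), 1)
    np.add.at(C_wk, (word_ids, z), 1)
    C_k = C_wk.sum(axis=0)

    for _ in range(n_iterations):
        u = rng.random(n_tokens)
        _gibbs_sweep(doc_ids, word_ids, z, C_dk, C_wk, C_k, alpha, beta, u)

    theta_mean = None
    if n_average > 0:
        acc = np.zeros((D, K))
        lengths = C_dk.sum(axis=1, keepdims=True).astype(float)
        for _ in range(n_average):
            u = rng.random(n_tokens)
            _gibbs_sweep(doc_ids, word_ids, z, C_dk, C_wk, C_k, alpha, beta, u)
            acc += (C_dk + alpha) / (lengths + K * alpha)
        theta_mean = acc / n_average

    return TopicModel(
        K=K, alpha=alpha, beta=beta, C_dk=C_dk, C_wk=C_wk, vocab=vocab,
        assignments=z, doc_ids=doc_ids, word_ids=word_ids, seed=seed,
        theta_mean=theta_mean,
    )


def doc_topic_features(model: TopicModel, d: int) -> np.ndarray:
    """Smoothed topic proportions of document ``d``; sums to 1."""
    counts = model.C_dk[d].astype(float)
    return (counts + model.alpha) / (counts.sum() + model.K * model.alpha)


def doc_topic_matrix(model: TopicModel) -> np.ndarray:
    """All documents' topic-proportion features, D x K.

    Uses the sweep-averaged posterior mean when the model was fitted
    with ``n_average > 0``, otherwise the final-state estimate.
    """
    if model.theta_mean is not None:
        return model.theta_mean
    counts = model.C_dk.astype(float)
    return (counts + model.alpha) / (
        counts.sum(axis=1, keepdims=True) + model.K * model.alpha
    )


def topic_word_dist(model: TopicModel, k: int) -> np.ndarray:
    """Smoothed word distribution of topic ``k``; sums to 1."""
    counts = model.C_wk[:, k].astype(float)
    return (counts + model.beta) / (counts.sum() + len(model.vocab) * model.beta)


def topic_word_matrix(model: TopicModel) -> np.ndarray:
    """All topics' word distributions, K x V (rows sum to 1)."""
    counts = model.C_wk.T.astype(float)
    return (counts + model.beta) / (
        counts.sum(axis=1, keepdims=True) + len(model.vocab) * model.beta
    )


def infer_doc_topics(
    model: TopicModel,
    tokens,
    n_iterations: int = 50,
    seed: int = 0,
    n_average: int = 0,
) -> np.ndarray:
    """Fold a held-out document into a fitted model.

    Gibbs-samples the new document's assignments against frozen training
    word-topic counts; out-of-vocabulary tokens are skipped.  An empty or
    all-OOV document gets the uniform topic vector.  With ``n_average >
    0`` the estimate is averaged over that many post-burn-in sweeps
    (``n_iterations`` acting as burn-in).
    """
    widx = model.word_index()
    word_ids = np.array([widx[w] for w in tokens if w in widx], dtype=np.int64)
    K = model.K
    if word_ids.size == 0:
        return np.full(K, 1.0 / K)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=word_ids.size).astype(np.int64)
    c_local = np.bincount(z, minlength=K).astype(np.int64)
    C_k = model.C_k
    for _ in range(n_iterations):
        u = rng.random(word_ids.size)
        _foldin_sweep(word_ids, z, c_local, model.C_wk, C_k, model.alpha, model.beta, u)
    if n_average > 0:
        acc = np.zeros(K)
        n_tok = float(word_ids.size)
        for _ in range(n_average):
            u = rng.random(word_ids.size)
            _foldin_sweep(word_ids, z, c_local, model.C_wk, C_k,
                          model.alpha, model.beta, u)
            acc += (c_local + model.alpha) / (n_tok + K * model.alpha)
        return acc / n_average
    counts = c_local.astype(float)
    return (counts + model.alpha) / (counts.sum() + K * model.alpha)


def log_likelihood(model: TopicModel) -> float:
    """Corpus log-likelihood under the current point estimates."""
    theta = doc_topic_matrix(model)  # D x K
    phi = topic_word_matrix(model)  # K x V
    p_tok = np.einsum(
        "tk,kt->t", theta[model.doc_ids], phi[:, model.word_ids]
    )
    return float(np.log(p_tok).sum())
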