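"""Skip-gram word embeddings with mean-pooled document vectors.

The skip-gram objective maximises the average log-probability of
context words within a window c of each corpus position, where the
conditional probability is the softmax over output vectors:

    p(w_O | w_I) = exp(v'_{w_O} · v_{w_I}) / Σ_w exp(v'_w · v_{w_I}).

Two trainers are provided: the exact softmax (gradient of the objective
above, feasible at synthetic vocabulary sizes and used by verification
tests) and negative sampling (the usual fast approximation, default for
experiment runs).  Document vectors are the arithmetic mean of the input
vectors of in-vocabulary tokens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .records import EMRecord


@dataclass
class EmbeddingModel:
    """Trained skip-gram state: input and output vector tables."""

    vocab: list[str]
    input_vectors: np.ndarray  # W x T
    output_vectors: np.ndarray  # W x T
    window: int
    seed: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def word_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocab)}


def _as_docs(corpus) -> list[list[str]]:
    return [
        item.tokens() if isinstance(item, EMRecord) else list(item) for item in corpus
    ]


def _training_pairs(docs, widx, window) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for doc in docs:
        ids = [widx[w] for w in doc]
        n = len(ids)
        for t in range(n):
            lo = max(0, t - window)
            hi = min(n, t + window + 1)
            for j in range(lo, hi):
                if j != t:
                    centers.append(ids[t])
                    contexts.append(ids[j])
    return (
        np.asarray(centers, dtype=np.int64),
        np.asarray(contexts, dtype=np.int64),
    )


@njit(cache=False)
def _train_exact(centers, contexts, Vin, Vout, lrs):
    W, T = Vin.shape
    for i in range(centers.shape[0]):
        c = centers[i]
        o = contexts[i]
        lr = lrs[i]
        v = Vin[c].copy()
        logits = Vout @ v
        m = logits.max()
        e = np.exp(logits - m)
        p = e / e.sum()
        # input-vector gradient: v'_o - E_p[v'_w]
        gin = Vout[o] - p @ Vout
        for w in range(W):
            coef = lr * ((1.0 if w == o else 0.0) - p[w])
            for t in range(T):
                Vout[w, t] += coef * v[t]
        for t in range(T):
            Vin[c, t] += lr * gin[t]


@njit(cache=False)
def _train_negative(centers, contexts, negatives, Vin, Vout, lrs):
    T = Vin.shape[1]
    n_neg = negatives.shape[1]
    for i in range(centers.shape[0]):
        c = centers[i]
        lr = lrs[i]
        v = Vin[c]
        gin = np.zeros(T)
        for s in range(n_neg + 1):
            if s == 0:
                target = contexts[i]
                label = 1.0
            else:
                target = negatives[i, s - 1]
                if target == contexts[i]:
                    continue
                label = 0.0
            dot = 0.0
            for t in range(T):
                dot += v[t] * Vout[target, t]
            # logistic gradient
            f = 1.0 / (1.0 + np.exp(-dot))
            g = lr * (label - f)
            for t in range(T):
                gin[t] += g * Vout[target, t]
                Vout[target, t] += g * v[t]
        for t in range(T):
            Vin[c, t] += gin[t]


def fit_skipgram(
    corpus,
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.025,
    n_negative: int = 5,
    seed: int = 0,
    track_objective: bool = False,
) -> EmbeddingModel:
    """Train skip-gram vectors by seeded stochastic gradient ascent.

    With ``n_negative = 0`` each update uses the exact softmax gradient;
    otherwise ``n_negative`` noise words per pair are drawn from the
    unigram^0.75 distribution.  The learning rate decays linearly over
    all updates.  ``track_objective`` records the exact-softmax
    objective after each epoch (quadratic in vocab size; meant for small
    corpora).
    """
    if dim < 1 or window < 1:
        raise ValueError("dim and window must be >= 1")
    docs = _as_docs(corpus)
    if not docs:
        raise ValueError("corpus must be non-empty")
    vocab = sorted({w for doc in docs for w in doc})
    if not vocab:
        raise ValueError("empty vocabulary: corpus has no tokens")
    widx = {w: i for i, w in enumerate(vocab)}
    centers, contexts = _training_pairs(docs, widx, window)
    if centers.size == 0:
        raise ValueError("no (center, context) training pairs; corpus too short")

    W = len(vocab)
    rng = np.random.default_rng(seed)
    Vin = (rng.random((W, dim)) - 0.5) / dim
    Vout = np.zeros((W, dim))

    counts = np.bincount(centers, minlength=W).astype(float)
    noise = counts**0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    n_pairs = centers.size
    total = epochs * n_pairs
    min_lr = learning_rate * 1e-4
    history: list[float] = []
    done = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        ctr = centers[order]
        ctx = contexts[order]
        lrs = learning_rate + (min_lr - learning_rate) * (
            (done + np.arange(n_pairs)) / max(total - 1, 1)
        )
        if n_negative > 0:
            negs = np.searchsorted(
                noise_cdf, rng.random((n_pairs, n_negative)), side="right"
            ).astype(np.int64)
            np.clip(negs, 0, W - 1, out=negs)
            _train_negative(ctr, ctx, negs, Vin, Vout, lrs)
        else:
            _train_exact(ctr, ctx, Vin, Vout, lrs)
        done += n_pairs
        if track_objective:
            history.append(skipgram_objective(Vin, Vout, centers, contexts))

    return EmbeddingModel(
        vocab=vocab, input_vectors=Vin, output_vectors=Vout,
        window=window, seed=seed, objective_history=history,
    )


def softmax_prob(model: EmbeddingModel, w_I: str, w_O: str) -> float:
    """Exact conditional probability p(w_O | w_I) under the model."""
    widx = model.word_index()
    try:
        i, o = widx[w_I], widx[w_O]
    except KeyError as exc:
        raise LookupError(f"unknown word: {exc.args[0]!r}") from exc
    logits = model.output_vectors @ model.input_vectors[i]
    logits -= logits.max()
    e = np.exp(logits)
    return float(e[o] / e.sum())


def doc_vector(model: EmbeddingModel, tokens) -> np.ndarray:
    """Mean input vector of in-vocabulary tokens (zeros if none)."""
    widx = model.word_index()
    ids = [widx[w] for w in tokens if w in widx]
    if not ids:
        warnings.warn("document has no in-vocabulary tokens; zero vector returned")
        return np.zeros(model.dim)
    return model.input_vectors[np.asarray(ids)].mean(axis=0)


def doc_vector_matrix(model: EmbeddingModel, docs) -> np.ndarray:
    """Stacked document vectors for a list of token lists or records."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.vstack([doc_vector(model, d) for d in _as_docs(docs)])


# ---------------------------------------------------------------------------
# exact-softmax objective, for verification and gradient checks
# ---------------------------------------------------------------------------


def skipgram_objective(
    Vin: np.ndarray, Vout: np.ndarray, centers: np.ndarray, contexts: np.ndarray
) -> float:
    """Mean log p(context | center) under the exact softmax."""
    logits = Vin[centers] @ Vout.T  # n_pairs x W
    logits -= logits.max(axis=1, keepdims=True)
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return float(logp[np.arange(centers.size), contexts].mean())


def skipgram_objective_grad(
    Vin: np.ndarray, Vout: np.ndarray, centers: np.ndarray, contexts: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Objective and its analytic gradients w.r.t. both vector tables."""
    n = centers.size
    logits = Vin[centers] @ Vout.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)  # n x W
    logp = np.log(p[np.arange(n), contexts])
    obj = float(logp.mean())

    resid = -p
    resid[np.arange(n), contexts] += 1.0  # (onehot - p), n x W
    g_in_pairs = resid @ Vout / n  # n x T
    gVin = np.zeros_like(Vin)
    np.add.at(gVin, centers, g_in_pairs)
    gVout = resid.T @ Vin[centers] / n  # W x T
    return obj, gVin, gVout


def training_pairs(corpus, window: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Expose the (vocab, centers, contexts) arrays used in training."""
    docs = _as_docs(corpus)
    vocab = sorted({w for doc in docs for w in doc})
    widx = {w: i for i, w in enumerate(vocab)}
    centers, contexts = _training_pairs(docs, widx, window)
    return vocab, centers, contexts
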