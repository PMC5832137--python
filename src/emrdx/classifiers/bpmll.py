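"""Backpropagation multilabel learning (BP-MLL).

A single-hidden-layer feed-forward network (tanh activations throughout)
trained on the pairwise exponential ranking loss

    E_i = (1 / (|Y_i|·|Ȳ_i|)) · Σ_{k∈Y_i} Σ_{l∈Ȳ_i} exp(−(c_k − c_l)),

which pushes the network output for every relevant label above the
output for every irrelevant one.  Instances whose label row is all-
positive or all-negative have no (relevant, irrelevant) pairs and are
skipped (and flagged) during training.  Because the loss constrains only
the ranking, a bipartition threshold t(x) is fitted afterwards by linear
least squares from score rows to each training instance's optimal
separating threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def bpmll_loss(scores_row: np.ndarray, label_row: np.ndarray) -> float:
    """Pairwise exponential ranking loss of one instance."""
    c = np.asarray(scores_row, dtype=float)
    y = np.asarray(label_row).astype(bool)
    pos, neg = c[y], c[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("label row needs at least one positive and one negative label")
    diff = pos[:, None] - neg[None, :]
    return float(np.exp(-diff).sum() / (pos.size * neg.size))


def sum_squares_loss(scores_row: np.ndarray, target_row: np.ndarray) -> float:
    """Legacy per-instance sum-of-squares objective Σ_j (c_j − d_j)²."""
    c = np.asarray(scores_row, dtype=float)
    d = np.asarray(target_row, dtype=float)
    return float(((c - d) ** 2).sum())


@dataclass
class BPMLLModel:
    W1: np.ndarray  # d x h
    b1: np.ndarray  # h
    W2: np.ndarray  # h x Q
    b2: np.ndarray  # Q
    threshold_coef: np.ndarray  # Q + 1 linear threshold function
    skipped_rows: np.ndarray  # training rows without label pairs
    feat_mean: np.ndarray  # standardisation learned from training features
    feat_scale: np.ndarray
    seed: int

    @property
    def n_labels(self) -> int:
        return self.W2.shape[1]


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(flat: np.ndarray, d: int, h: int, Q: int):
    i = 0
    W1 = flat[i : i + d * h].reshape(d, h); i += d * h
    b1 = flat[i : i + h]; i += h
    W2 = flat[i : i + h * Q].reshape(h, Q); i += h * Q
    b2 = flat[i : i + Q]
    return W1, b1, W2, b2


def _forward(X, W1, b1, W2, b2):
    H = np.tanh(X @ W1 + b1)
    C = np.tanh(H @ W2 + b2)
    return H, C


def bpmll_objective_grad(
    flat: np.ndarray, X: np.ndarray, Y: np.ndarray, hidden: int, l2: float
) -> tuple[float, np.ndarray]:
    """Mean pairwise ranking loss + L2 penalty, with analytic gradient.

    All rows of ``Y`` must carry at least one positive and one negative
    label.  The gradient is exact (used both by training and by
    finite-difference verification).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y).astype(bool)
    p, d = X.shape
    Q = Y.shape[1]
    W1, b1, W2, b2 = _unpack(flat, d, hidden, Q)
    H, C = _forward(X, W1, b1, W2, b2)

    pos_counts = Y.sum(axis=1)
    neg_counts = Q - pos_counts
    if np.any(pos_counts == 0) or np.any(neg_counts == 0):
        raise ValueError("every row must have >= 1 positive and >= 1 negative label")
    norm = (pos_counts * neg_counts).astype(float)

    # E_i factorises: (Σ_{k∈Y} e^{-c_k}) (Σ_{l∈Ȳ} e^{c_l}) / (|Y||Ȳ|)
    Eneg = np.where(Y, np.exp(-C), 0.0)
    Epos = np.where(~Y, np.exp(C), 0.0)
    S_pos = Eneg.sum(axis=1)
    S_neg = Epos.sum(axis=1)
    losses = S_pos * S_neg / norm
    obj = float(losses.mean()) + l2 * (float((W1**2).sum()) + float((W2**2).sum()))

    dC = np.where(
        Y,
        -Eneg * S_neg[:, None],
        Epos * S_pos[:, None],
    ) / (norm[:, None] * p)

    dZ2 = dC * (1.0 - C**2)
    gW2 = H.T @ dZ2 + 2.0 * l2 * W2
    gb2 = dZ2.sum(axis=0)
    dH = dZ2 @ W2.T
    dZ1 = dH * (1.0 - H**2)
    gW1 = X.T @ dZ1 + 2.0 * l2 * W1
    gb1 = dZ1.sum(axis=0)
    return obj, _pack(gW1, gb1, gW2, gb2)


def _optimal_thresholds(scores: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-instance threshold minimising bipartition errors against Y.

    Candidates are midpoints of adjacent sorted scores plus sentinels;
    among minimisers the middle of the optimal interval is taken.
    """
    Y = Y.astype(bool)
    out = np.empty(scores.shape[0])
    for i, (row, y) in enumerate(zip(scores, Y)):
        srt = np.sort(np.unique(row))
        cands = np.concatenate([
            [srt[0] - 1.0],
            (srt[:-1] + srt[1:]) / 2.0,
            [srt[-1] + 1.0],
        ])
        errs = np.array([
            int(np.sum(row[y] <= t) + np.sum(row[~y] > t)) for t in cands
        ])
        out[i] = cands[int(np.argmin(errs))]
    return out


def bpmll_fit(
    X: np.ndarray,
    Y: np.ndarray,
    hidden_frac: float = 0.5,
    epochs: int = 500,
    learning_rate: float = 2.0,
    l2: float = 1e-5,
    seed: int = 0,
) -> BPMLLModel:
    """Train a BP-MLL network by full-batch gradient descent.

    Features are standardised internally (zero mean, unit variance per
    column, learned from the training set) so the pairwise exponential
    loss sees inputs on a common scale regardless of feature type.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y).astype(np.int8)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    feat_mean = X.mean(axis=0)
    feat_scale = X.std(axis=0)
    feat_scale[feat_scale == 0] = 1.0
    X = (X - feat_mean) / feat_scale
    p, d = X.shape
    Q = Y.shape[1]
    pos = Y.sum(axis=1)
    eligible = (pos >= 1) & (pos <= Q - 1)
    skipped = np.flatnonzero(~eligible)
    if skipped.size:
        warnings.warn(
            f"{skipped.size} instance(s) without (relevant, irrelevant) "
            "label pairs skipped in BP-MLL training"
        )
    if not eligible.any():
        raise ValueError("no training instance has both positive and negative labels")
    Xe, Ye = X[eligible], Y[eligible]

    hidden = max(2, int(np.ceil(hidden_frac * d)))
    rng = np.random.default_rng(seed)
    scale = 0.05
    flat = _pack(
        rng.uniform(-scale, scale, size=(d, hidden)),
        rng.uniform(-scale, scale, size=hidden),
        rng.uniform(-scale, scale, size=(hidden, Q)),
        rng.uniform(-scale, scale, size=Q),
    )
    for _ in range(epochs):
        _, grad = bpmll_objective_grad(flat, Xe, Ye, hidden, l2)
        flat = flat - learning_rate * grad

    W1, b1, W2, b2 = (a.copy() for a in _unpack(flat, d, hidden, Q))
    _, scores = _forward(Xe, W1, b1, W2, b2)
    ts = _optimal_thresholds(scores, Ye)
    A = np.hstack([scores, np.ones((scores.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(A, ts, rcond=None)
    return BPMLLModel(W1=W1, b1=b1, W2=W2, b2=b2, threshold_coef=coef,
                      skipped_rows=skipped, feat_mean=feat_mean,
                      feat_scale=feat_scale, seed=seed)


def bpmll_score(model: BPMLLModel, X: np.ndarray) -> np.ndarray:
    """Network outputs (the ranking function f), p x Q."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X = (X - model.feat_mean) / model.feat_scale
    _, C = _forward(X, model.W1, model.b1, model.W2, model.b2)
    return C


def bpmll_predict(model: BPMLLModel, X: np.ndarray) -> np.ndarray:
    """Bipartition: scores above the learned linear threshold t(x)."""
    scores = bpmll_score(model, X)
    A = np.hstack([scores, np.ones((scores.shape[0], 1))])
    t = A @ model.threshold_coef
    return (scores > t[:, None]).astype(np.int8)
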