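"""Multilabel k-nearest neighbour (MLkNN).

For each label j the method is a small Bayesian classifier on the count
c of positive neighbours among a query's k nearest training points:

    prior        P(H_j)        = (s + Σ_i Y_ij) / (2s + p)
    conditionals P(E_c | H_j)  = (s + κ_j[c]) / (s·(k+1) + Σ_c κ_j[c])

with Laplace smoothing s, κ_j[c] counting training instances with label
j whose own k neighbours (self excluded) include c positives.  The score
is the posterior P(H_j | E_c); bipartition is posterior > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class MLkNNModel:
    k: int
    s: float
    priors: np.ndarray  # Q, P(H_j)
    cond_pos: np.ndarray  # Q x (k+1), P(E_c | H_j)
    cond_neg: np.ndarray  # Q x (k+1), P(E_c | ¬H_j)
    X_train: np.ndarray
    Y_train: np.ndarray
    nn: NearestNeighbors

    @property
    def n_labels(self) -> int:
        return self.Y_train.shape[1]


def _self_excluded_neighbors(nn: NearestNeighbors, X: np.ndarray, k: int) -> np.ndarray:
    """k nearest training neighbours of each training point, self excluded."""
    _, idx = nn.kneighbors(X, n_neighbors=k + 1)
    p = X.shape[0]
    out = np.empty((p, k), dtype=np.int64)
    for i in range(p):
        row = idx[i]
        row = row[row != i][:k]
        if row.size < k:  # self not returned (duplicate points); drop last
            row = idx[i][:k]
        out[i] = row
    return out


def mlknn_fit(X: np.ndarray, Y: np.ndarray, k: int = 10, s: float = 1.0) -> MLkNNModel:
    """Estimate priors and neighbour-count conditionals from training data."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y).astype(np.int8)
    p, Q = Y.shape[0], Y.shape[1]
    if k >= p:
        raise ValueError(f"k = {k} must be smaller than the number of instances {p}")
    if s <= 0:
        raise ValueError("smoothing s must be positive")

    priors = (s + Y.sum(axis=0)) / (2.0 * s + p)

    nn = NearestNeighbors(metric="euclidean").fit(X)
    neigh = _self_excluded_neighbors(nn, X, k)
    # c_counts[i, j] = positives for label j among i's k neighbours
    c_counts = Y[neigh].sum(axis=1)  # p x Q

    kappa_pos = np.zeros((Q, k + 1))
    kappa_neg = np.zeros((Q, k + 1))
    for j in range(Q):
        pos_mask = Y[:, j] == 1
        kappa_pos[j] = np.bincount(c_counts[pos_mask, j], minlength=k + 1)
        kappa_neg[j] = np.bincount(c_counts[~pos_mask, j], minlength=k + 1)
    cond_pos = (s + kappa_pos) / (s * (k + 1) + kappa_pos.sum(axis=1, keepdims=True))
    cond_neg = (s + kappa_neg) / (s * (k + 1) + kappa_neg.sum(axis=1, keepdims=True))

    return MLkNNModel(k=k, s=s, priors=priors, cond_pos=cond_pos,
                      cond_neg=cond_neg, X_train=X, Y_train=Y, nn=nn)


def mlknn_score(model: MLkNNModel, X: np.ndarray) -> np.ndarray:
    """Posterior P(H_j | E_c) for each query row and label."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, idx = model.nn.kneighbors(X, n_neighbors=model.k)
    c_counts = model.Y_train[idx].sum(axis=1)  # n x Q
    Q = model.n_labels
    cols = np.arange(Q)
    num = model.priors * model.cond_pos[cols, c_counts]
    den = num + (1.0 - model.priors) * model.cond_neg[cols, c_counts]
    return num / den


def mlknn_predict(model: MLkNNModel, X: np.ndarray) -> np.ndarray:
    """Bipartition: posterior above 1/2."""
    return (mlknn_score(model, X) > 0.5).astype(np.int8)
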