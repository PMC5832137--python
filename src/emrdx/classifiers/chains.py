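"""Classifier chains: one binary learner per label, linked in sequence.

Classifier j in the chain consumes the feature vector augmented with the
(true, at training time; predicted, at inference time) values of every
earlier label in the chain.  Scores are the positive-class probabilities
reported in the original label order; bipartition is probability > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression


def default_base_learner():
    return LogisticRegression(max_iter=1000, C=10.0)


class _ConstantProb:
    """Stand-in for a base learner on a single-class label column."""

    def __init__(self, value: int) -> None:
        self.value = int(value)

    def predict_proba_pos(self, X) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], float(self.value))


@dataclass
class CCModel:
    chain_order: np.ndarray  # permutation of 0..Q-1
    estimators: list[object]  # per chain position
    n_features: int
    seed: int

    @property
    def n_labels(self) -> int:
        return self.chain_order.size


def _pos_proba(clf, X: np.ndarray) -> np.ndarray:
    if isinstance(clf, _ConstantProb):
        return clf.predict_proba_pos(X)
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


def cc_fit(
    X: np.ndarray,
    Y: np.ndarray,
    chain_order=None,
    base_learner=None,
    seed: int = 0,
) -> CCModel:
    """Train the chain; single-class columns get constant predictors."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y).astype(np.int8)
    Q = Y.shape[1]
    if chain_order is None:
        order = np.arange(Q)
    elif isinstance(chain_order, str) and chain_order == "random":
        order = np.random.default_rng(seed).permutation(Q)
    else:
        order = np.asarray(chain_order, dtype=np.int64)
        if sorted(order.tolist()) != list(range(Q)):
            raise ValueError("chain_order must be a permutation of 0..Q-1")
    if base_learner is None:
        base_learner = default_base_learner()

    estimators: list[object] = []
    for pos, j in enumerate(order):
        feats = np.hstack([X, Y[:, order[:pos]]]) if pos else X
        col = Y[:, j]
        if len(np.unique(col)) < 2:
            warnings.warn(
                f"label column {j} is constant; predicting its constant class"
            )
            estimators.append(_ConstantProb(col[0]))
            continue
        clf = clone(base_learner)
        clf.fit(feats, col)
        estimators.append(clf)
    return CCModel(chain_order=order, estimators=estimators,
                   n_features=X.shape[1], seed=seed)


def cc_score(model: CCModel, X: np.ndarray) -> np.ndarray:
    """Propagate hard predictions down the chain; report probabilities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    Q = model.n_labels
    scores = np.zeros((n, Q))
    hard = np.zeros((n, 0), dtype=np.int8)
    for pos, j in enumerate(model.chain_order):
        feats = np.hstack([X, hard]) if pos else X
        proba = _pos_proba(model.estimators[pos], feats)
        scores[:, j] = proba
        hard = np.hstack([hard, (proba > 0.5).astype(np.int8)[:, None]])
    return scores


def cc_predict(model: CCModel, X: np.ndarray) -> np.ndarray:
    """Bipartition: chained positive-class probability above 1/2."""
    return (cc_score(model, X) > 0.5).astype(np.int8)
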