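"""RAkEL: ensemble of label-powerset classifiers on random k-labelsets.

``m`` distinct labelsets of size ``k_r`` are drawn; for each one a
multiclass base classifier is trained on the powerset of observed label
combinations restricted to that set.  A label's score is the fraction of
labelsets containing it whose classifier votes it positive; bipartition
is score > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression


def default_base_learner():
    return LogisticRegression(max_iter=1000, C=10.0)


@dataclass
class _PowersetMember:
    labelset: tuple[int, ...]
    classes: np.ndarray  # class id -> bit pattern rows (n_classes x k_r)
    clf: object | None  # None when only one combination was observed
    constant_class: int


@dataclass
class RAkELModel:
    members: list[_PowersetMember]
    n_labels: int
    k_r: int
    seed: int

    def coverage(self) -> np.ndarray:
        cov = np.zeros(self.n_labels, dtype=int)
        for mem in self.members:
            for j in mem.labelset:
                cov[j] += 1
        return cov


def _draw_labelsets(Q: int, k_r: int, m: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    total = comb(Q, k_r)
    if m > total:
        raise ValueError(f"m = {m} exceeds the {total} distinct labelsets of size {k_r}")
    chosen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < m:
        cand = tuple(sorted(rng.choice(Q, size=k_r, replace=False).tolist()))
        if cand not in chosen:
            chosen.add(cand)
            out.append(cand)
    return out


def rakel_fit(
    X: np.ndarray,
    Y: np.ndarray,
    k_r: int = 3,
    m: int | None = None,
    base_learner=None,
    seed: int = 0,
) -> RAkELModel:
    """Train the labelset ensemble; warns if any label is uncovered."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y).astype(np.int8)
    Q = Y.shape[1]
    if not 1 <= k_r <= Q:
        raise ValueError("k_r must be in [1, Q]")
    if m is None:
        m = min(2 * Q, comb(Q, k_r))
    if base_learner is None:
        base_learner = default_base_learner()
    rng = np.random.default_rng(seed)
    labelsets = _draw_labelsets(Q, k_r, m, rng)

    members: list[_PowersetMember] = []
    for ls in labelsets:
        sub = Y[:, ls]
        patterns, class_ids = np.unique(sub, axis=0, return_inverse=True)
        if patterns.shape[0] == 1:
            members.append(_PowersetMember(ls, patterns, None, 0))
            continue
        clf = clone(base_learner)
        clf.fit(X, class_ids)
        members.append(_PowersetMember(ls, patterns, clf, -1))

    model = RAkELModel(members=members, n_labels=Q, k_r=k_r, seed=seed)
    uncovered = np.flatnonzero(model.coverage() == 0)
    if uncovered.size:
        warnings.warn(
            f"labels {uncovered.tolist()} appear in no labelset; their score is 0"
        )
    return model


def rakel_score(model: RAkELModel, X: np.ndarray) -> np.ndarray:
    """Vote fraction per label over the labelsets containing it."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    votes = np.zeros((n, model.n_labels))
    appear = np.maximum(model.coverage(), 1)
    for mem in model.members:
        if mem.clf is None:
            bits = np.tile(mem.classes[mem.constant_class], (n, 1))
        else:
            pred = mem.clf.predict(X)
            bits = mem.classes[pred]
        for col, j in enumerate(mem.labelset):
            votes[:, j] += bits[:, col]
    return votes / appear


def rakel_predict(model: RAkELModel, X: np.ndarray) -> np.ndarray:
    """Bipartition: majority of the voting labelsets."""
    return (rakel_score(model, X) > 0.5).astype(np.int8)
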