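"""Seeded random-score baseline, the floor every real classifier must beat."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RandomScoreModel:
    n_labels: int
    seed: int


def random_fit(X: np.ndarray, Y: np.ndarray, seed: int = 0) -> RandomScoreModel:
    return RandomScoreModel(n_labels=np.asarray(Y).shape[1], seed=seed)


def random_score(model: RandomScoreModel, X: np.ndarray) -> np.ndarray:
    n = np.atleast_2d(np.asarray(X)).shape[0]
    rng = np.random.default_rng(model.seed)
    return rng.random((n, model.n_labels))


def random_predict(model: RandomScoreModel, X: np.ndarray) -> np.ndarray:
    return (random_score(model, X) > 0.5).astype(np.int8)
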