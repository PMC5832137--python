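"""Deterministic label ranking from score rows."""

from __future__ import annotations

import numpy as np


def rank_labels(score_row: np.ndarray) -> np.ndarray:
    """1-based ranks by descending score; ties broken by label index."""
    s = np.asarray(score_row, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    order = np.lexsort((np.arange(s.size), -s))
    ranks = np.empty(s.size, dtype=np.int64)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


def rank_matrix(scores: np.ndarray) -> np.ndarray:
    """Row-wise :func:`rank_labels` over a score matrix."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return np.vstack([rank_labels(row) for row in scores])
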