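"""Ranking-based multilabel evaluation and cross-validated reporting.

The five measures are the standard multilabel set: Hamming loss (density
of the symmetric difference between the predicted and true label sets),
one-error (top-ranked label irrelevant), coverage (average rank depth
needed to capture all relevant labels, minus one), ranking loss
(fraction of mis-ordered (relevant, irrelevant) pairs) and average
precision (mean precision of the ranked list truncated at each relevant
label).  Ranks come from :func:`emrdx.classifiers.rank_labels`, which
breaks score ties by label index so every measure is deterministic.

Degenerate rows — an empty relevant set, or (for ranking loss) a full
one — are excluded from the affected measure with a warning rather than
failing the evaluation, since frequency-filtered label sets can produce
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    bpmll_fit, bpmll_predict, bpmll_score,
    cc_fit, cc_predict, cc_score,
    mlknn_fit, mlknn_predict, mlknn_score,
    rakel_fit, rakel_predict, rakel_score,
    random_fit, random_predict, random_score,
    rank_matrix,
)
from .embed import doc_vector_matrix, fit_skipgram
from .lda import doc_topic_matrix, fit_lda, infer_doc_topics
from .preprocess import LabelSpace, build_label_space, label_matrix
from .records import EMRecord

METRIC_NAMES = (
    "hamming_loss", "one_error", "coverage", "ranking_loss", "average_precision",
)
#: directions for "best value" flagging: -1 smaller-better, +1 bigger-better
METRIC_DIRECTIONS = {
    "hamming_loss": -1, "one_error": -1, "coverage": -1,
    "ranking_loss": -1, "average_precision": 1,
}


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(a))
    b = np.atleast_2d(np.asarray(b))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _warn_excluded(n: int, what: str) -> None:
    if n:
        warnings.warn(f"{n} instance(s) with {what} excluded from the metric")


def hamming_loss(bipartition: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-label disagreement |h(x) Δ Y| / Q."""
    h, y = _check_shapes(bipartition, truth)
    return float((h.astype(bool) ^ y.astype(bool)).mean())


def one_error(scores: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of instances whose rank-1 label is irrelevant."""
    s, y = _check_shapes(scores, truth)
    y = y.astype(bool)
    keep = y.any(axis=1)
    _warn_excluded(int((~keep).sum()), "no relevant label")
    s, y = s[keep], y[keep]
    if s.shape[0] == 0:
        return float("nan")
    ranks = rank_matrix(s)
    top = ranks == 1
    hit = (top & y).any(axis=1)
    return float(1.0 - hit.mean())


def coverage(scores: np.ndarray, truth: np.ndarray) -> float:
    """Average worst rank of a relevant label, minus one."""
    s, y = _check_shapes(scores, truth)
    y = y.astype(bool)
    keep = y.any(axis=1)
    _warn_excluded(int((~keep).sum()), "no relevant label")
    s, y = s[keep], y[keep]
    if s.shape[0] == 0:
        return float("nan")
    ranks = rank_matrix(s)
    worst = np.where(y, ranks, 0).max(axis=1)
    return float((worst - 1).mean())


def ranking_loss(scores: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of (relevant, irrelevant) pairs with f(rel) <= f(irr)."""
    s, y = _check_shapes(scores, truth)
    y = y.astype(bool)
    n_pos = y.sum(axis=1)
    keep = (n_pos >= 1) & (n_pos <= y.shape[1] - 1)
    _warn_excluded(int((~keep).sum()), "no (relevant, irrelevant) pair")
    s, y = s[keep], y[keep]
    if s.shape[0] == 0:
        return float("nan")
    vals = []
    for row, yr in zip(s, y):
        pos, neg = row[yr], row[~yr]
        bad = (pos[:, None] <= neg[None, :]).sum()
        vals.append(bad / (pos.size * neg.size))
    return float(np.mean(vals))


def average_precision(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mean precision of the ranked list at each relevant label's rank."""
    s, y = _check_shapes(scores, truth)
    y = y.astype(bool)
    keep = y.any(axis=1)
    _warn_excluded(int((~keep).sum()), "no relevant label")
    s, y = s[keep], y[keep]
    if s.shape[0] == 0:
        return float("nan")
    ranks = rank_matrix(s)
    vals = []
    for rr, yr in zip(ranks, y):
        rel_ranks = np.sort(rr[yr])
        prec = np.arange(1, rel_ranks.size + 1) / rel_ranks
        vals.append(prec.mean())
    return float(np.mean(vals))


def compute_all(scores: np.ndarray, bipartition: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """All five measures from a score matrix, bipartition and truth."""
    return {
        "hamming_loss": hamming_loss(bipartition, truth),
        "one_error": one_error(scores, truth),
        "coverage": coverage(scores, truth),
        "ranking_loss": ranking_loss(scores, truth),
        "average_precision": average_precision(scores, truth),
    }


# ---------------------------------------------------------------------------
# cross-validated pipeline evaluation
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """One feature-extractor + classifier combination to evaluate."""

    feature: str = "lda"  # "lda" | "word_vector"
    feature_params: dict = field(default_factory=dict)
    classifier: str = "mlknn"  # "bpmll" | "mlknn" | "rakel" | "cc" | "random"
    classifier_params: dict = field(default_factory=dict)


@dataclass
class MetricReport:
    """Per-fold metric values with mean ± sample standard deviation."""

    per_fold: dict[str, list[float]]
    n_folds: int
    seed: int

    def mean(self, name: str) -> float:
        return float(np.mean(self.per_fold[name]))

    def std(self, name: str) -> float:
        vals = self.per_fold[name]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, str]:
        return {
            name: f"{self.mean(name):.4f} ± {self.std(name):.4f}"
            for name in METRIC_NAMES
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold, index=[f"fold_{i}" for i in range(self.n_folds)])


_CLASSIFIERS = {
    "bpmll": (bpmll_fit, bpmll_score, bpmll_predict),
    "mlknn": (mlknn_fit, mlknn_score, mlknn_predict),
    "rakel": (rakel_fit, rakel_score, rakel_predict),
    "cc": (cc_fit, cc_score, cc_predict),
    "random": (random_fit, random_score, random_predict),
}

#: pipeline defaults: a sparse document-topic prior suits records that
#: mix only a few topics
CV_FEATURE_DEFAULTS = {
    "lda": {"K": 60, "alpha": 0.1, "beta": 0.01, "n_iterations": 450,
            "n_average": 50},
    "word_vector": {"dim": 100, "window": 5, "epochs": 10, "n_negative": 5},
}


def _derive_seed(seed: int, fold: int, salt: int = 0) -> int:
    return int((seed * 100003 + fold * 131 + salt) % (2**31 - 1))


def fold_indices(p: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of 0..p-1 into n_folds near-equal folds."""
    if n_folds < 2 or n_folds > p:
        raise ValueError("n_folds must be in [2, p]")
    perm = np.random.default_rng(seed).permutation(p)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def _extract_features(config, train_docs, test_docs, seed):
    params = dict(CV_FEATURE_DEFAULTS[config.feature])
    params.update(config.feature_params)
    if config.feature == "lda":
        infer_iters = params.pop("infer_iterations", 30)
        infer_avg = params.pop("infer_average", 30)
        model = fit_lda(train_docs, seed=seed, **params)
        Xtr = doc_topic_matrix(model)
        Xte = np.vstack([
            infer_doc_topics(model, doc, n_iterations=infer_iters,
                             n_average=infer_avg,
                             seed=_derive_seed(seed, i, salt=7))
            for i, doc in enumerate(test_docs)
        ]) if test_docs else np.empty((0, model.K))
        # Hellinger map: sqrt of topic proportions, so Euclidean
        # distances between feature rows track probability divergence
        return np.sqrt(Xtr), np.sqrt(Xte)
    if config.feature == "word_vector":
        model = fit_skipgram(train_docs, seed=seed, **params)
        return doc_vector_matrix(model, train_docs), doc_vector_matrix(model, test_docs)
    raise ValueError(f"unknown feature type {config.feature!r}")


def cross_validate(
    config: PipelineConfig,
    corpus: Sequence[EMRecord],
    n_folds: int = 10,
    seed: int = 0,
    space: LabelSpace | None = None,
) -> MetricReport:
    """Evaluate a pipeline with seeded k-fold cross-validation.

    Feature extractors and classifiers are fitted on each training fold
    only; held-out documents are projected through the fitted extractor
    (topic fold-in for LDA, vector averaging for embeddings), so no test
    token influences any fitted parameter.
    """
    if space is None:
        space = build_label_space(corpus)
    Y = label_matrix(corpus, space)
    p = len(corpus)
    folds = fold_indices(p, n_folds, seed)
    fit, score_fn, predict_fn = _CLASSIFIERS[config.classifier]
    docs = [rec.tokens() for rec in corpus]

    per_fold: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(p), test_idx)
        fseed = _derive_seed(seed, f)
        train_docs = [docs[i] for i in train_idx]
        test_docs = [docs[i] for i in test_idx]
        Xtr, Xte = _extract_features(config, train_docs, test_docs, fseed)
        Ytr, Yte = Y[train_idx], Y[test_idx]

        params = dict(config.classifier_params)
        if config.classifier in ("bpmll", "rakel", "cc", "random"):
            params.setdefault("seed", fseed)
        model = fit(Xtr, Ytr, **params)
        scores = score_fn(model, Xte)
        biparts = predict_fn(model, Xte)
        for name, val in compute_all(scores, biparts, Yte).items():
            per_fold[name].append(val)

    return MetricReport(per_fold=per_fold, n_folds=n_folds, seed=seed)
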