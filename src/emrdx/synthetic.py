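"""Seeded synthetic corpus generator with planted topic–label structure.

The real first-course corpora this package targets are never public, so
every downstream stage is exercised on generated data that reproduces the
statistics that matter for multilabel learning: a heavily skewed label
frequency distribution, per-record label cardinality between 1 and 8 with
mean ~2.67, and section text whose tokens are emitted by a latent topic
process tied to the record's labels.  Each label owns one dominant topic
(plus a small uniform noise floor), so diagnoses are statistically
recoverable from the text — the premise of the diagnosis-assistant task.

Generation is fully determined by ``SyntheticConfig.seed``: the same
config yields a byte-identical corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import SECTION_KEYS, EMRecord

#: cardinality distribution over 1..8 with mean 2.67
DEFAULT_CARDINALITY_DIST: tuple[float, ...] = (
    0.26, 0.29, 0.20, 0.12, 0.07, 0.03, 0.02, 0.01,
)

DEFAULT_SECTION_LENGTHS: dict[str, float] = {
    "chief_complaints": 40.0,
    "physical_exam": 35.0,
    "obstetric_exam": 35.0,
    "auxiliary_exam": 30.0,
}


class SyntheticConfigError(ValueError):
    """Raised for an inconsistent generator configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the generative process.

    Parameters
    ----------
    n_records:
        Number of records to emit.
    n_labels:
        Size Q of the planted label space.
    n_topics_true:
        Number of latent topics; defaults to one topic per label.
    vocab_size:
        Token alphabet size; tokens are rendered as ``w0017``-style strings.
    section_lengths:
        Mean token count per section (Poisson-distributed lengths).
    cardinality_dist:
        Probability vector over label counts 1..8 per record.
    label_skew:
        Exponent of the power-law label frequency distribution
        (weight of rank-r label ∝ r**-label_skew).
    affinity_noise:
        Fraction of each label's topic mass spread uniformly over all
        topics; the rest sits on the label's dominant topic.
    dirichlet_alpha:
        Total smoothing mass spread uniformly over topics and added to
        each record's topic mixture before normalisation (so the noise
        fraction it induces does not grow with the topic count).
    dirichlet_beta:
        Concentration of the Dirichlet from which true topic-word rows
        are drawn (small values give well-separated topics).
    """

    n_records: int = 2000
    n_labels: int = 60
    n_topics_true: int | None = None
    vocab_size: int = 2000
    section_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTION_LENGTHS)
    )
    cardinality_dist: tuple[float, ...] = DEFAULT_CARDINALITY_DIST
    label_skew: float = 1.0
    affinity_noise: float = 0.05
    dirichlet_alpha: float = 0.05
    dirichlet_beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics_true is None:
            self.n_topics_true = self.n_labels
        if self.n_records < 0:
            raise SyntheticConfigError("n_records must be >= 0")
        for name in ("n_labels", "n_topics_true", "vocab_size"):
            if getattr(self, name) <= 0:
                raise SyntheticConfigError(f"{name} must be positive")
        if self.n_topics_true > self.vocab_size:
            raise SyntheticConfigError("n_topics_true must not exceed vocab_size")
        card = np.asarray(self.cardinality_dist, dtype=float)
        if card.ndim != 1 or len(card) > 8 or np.any(card < 0):
            raise SyntheticConfigError("cardinality_dist must be nonnegative over 1..8")
        if not math.isclose(card.sum(), 1.0, abs_tol=1e-9):
            raise SyntheticConfigError("cardinality_dist must sum to 1")
        max_card = int(np.max(np.nonzero(card)[0])) + 1 if card.any() else 0
        if max_card > self.n_labels:
            raise SyntheticConfigError(
                f"cardinality up to {max_card} requested but only "
                f"{self.n_labels} labels exist"
            )
        if self.dirichlet_alpha <= 0 or self.dirichlet_beta <= 0:
            raise SyntheticConfigError("dirichlet_alpha and dirichlet_beta must be > 0")
        if not 0.0 <= self.affinity_noise < 1.0:
            raise SyntheticConfigError("affinity_noise must be in [0, 1)")
        if set(self.section_lengths) != set(SECTION_KEYS):
            raise SyntheticConfigError(
                f"section_lengths must have exactly the keys {SECTION_KEYS}"
            )

    @property
    def mean_cardinality(self) -> float:
        card = np.asarray(self.cardinality_dist, dtype=float)
        return float(np.dot(card, np.arange(1, len(card) + 1)))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated corpus, for recovery tests."""

    topic_word_true: np.ndarray  # K_true x V, row-stochastic
    label_topic_affinity: np.ndarray  # Q x K_true, rows sum to 1
    per_record_labels: list[set[str]]
    labels: list[str]
    label_weights: np.ndarray  # planted sampling weights, descending


def label_name(i: int) -> str:
    return f"dx_{i:03d}"


def token_name(j: int) -> str:
    return f"w{j:04d}"


def generate_corpus(config: SyntheticConfig) -> tuple[list[EMRecord], SyntheticTruth]:
    """Generate a corpus plus its planted ground truth.

    The process: (1) label sampling weights follow a power law with
    exponent ``label_skew``; (2) each record draws a label cardinality
    from ``cardinality_dist`` and that many distinct labels proportional
    to weight; (3) the record's topic mixture is the normalised sum of
    its labels' affinity rows smoothed by ``dirichlet_alpha``; (4) every
    section token draws a topic from the mixture, then a word from the
    true topic-word distribution.
    """
    rng = np.random.default_rng(config.seed)
    Q = config.n_labels
    K = int(config.n_topics_true)
    V = config.vocab_size

    # planted structures
    topic_word = rng.dirichlet(np.full(V, config.dirichlet_beta), size=K)
    affinity = np.full((Q, K), config.affinity_noise / K)
    dominant = np.arange(Q) % K
    affinity[np.arange(Q), dominant] += 1.0 - config.affinity_noise

    weights = np.arange(1, Q + 1, dtype=float) ** (-config.label_skew)
    weights /= weights.sum()

    labels = [label_name(i) for i in range(Q)]
    tokens = [token_name(j) for j in range(V)]
    topic_cdf = np.cumsum(topic_word, axis=1)
    topic_cdf[:, -1] = 1.0

    card_support = np.arange(1, len(config.cardinality_dist) + 1)
    card_p = np.asarray(config.cardinality_dist, dtype=float)

    corpus: list[EMRecord] = []
    per_record_labels: list[set[str]] = []
    for i in range(config.n_records):
        c = int(rng.choice(card_support, p=card_p))
        lab_idx = rng.choice(Q, size=c, replace=False, p=weights)
        theta = affinity[lab_idx].sum(axis=0) + config.dirichlet_alpha / K
        theta /= theta.sum()

        lengths = {key: int(rng.poisson(config.section_lengths[key])) for key in SECTION_KEYS}
        n_tok = sum(lengths.values())
        zs = rng.choice(K, size=n_tok, p=theta) if n_tok else np.empty(0, dtype=int)
        word_ids = np.empty(n_tok, dtype=np.int64)
        us = rng.random(n_tok)
        for k in np.unique(zs):
            mask = zs == k
            word_ids[mask] = np.searchsorted(topic_cdf[k], us[mask], side="right")
        np.clip(word_ids, 0, V - 1, out=word_ids)

        sections: dict[str, list[str]] = {}
        pos = 0
        for key in SECTION_KEYS:
            n = lengths[key]
            sections[key] = [tokens[w] for w in word_ids[pos : pos + n]]
            pos += n

        rec_labels = {labels[j] for j in lab_idx}
        corpus.append(EMRecord(record_id=f"r{i:05d}", sections=sections, raw_labels=rec_labels))
        per_record_labels.append(rec_labels)

    truth = SyntheticTruth(
        topic_word_true=topic_word,
        label_topic_affinity=affinity / affinity.sum(axis=1, keepdims=True),
        per_record_labels=per_record_labels,
        labels=labels,
        label_weights=weights,
    )
    return corpus, truth
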