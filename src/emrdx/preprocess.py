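"""Record cleaning, sectioning, tokenisation and label standardisation.

The admitting-diagnosis strings attached to first-course records come
from many institutions with divergent writing habits, so the raw label
set is noisy: duplicates differ only in phrasing ("placenta previa" vs
"state of placenta previa"), some "diagnoses" are arithmetic results
(gestational age, gravida/para counts) rather than classes, and a long
tail of labels occurs once or twice.  This module standardises the label
space in three steps: pattern-based exclusion of calculated labels,
cosine-similarity merging of synonymous labels (single linkage over a
semantic-vector similarity), and frequency-floor reduction of the merged
space (the L2 -> L3 -> L4 progression).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .records import SECTION_KEYS, EMRecord


class StructureError(ValueError):
    """Raised when free text cannot be split into any known section."""


class EmptyLabelSpaceError(ValueError):
    """Raised when a frequency filter removes every label."""


# ---------------------------------------------------------------------------
# label space container
# ---------------------------------------------------------------------------


@dataclass
class LabelSpace:
    """Ordered, standardised label set defining label-matrix columns.

    ``labels`` are sorted by descending corpus frequency (ties broken
    lexicographically); ``merge_map`` sends every raw label string to its
    canonical form.
    """

    labels: list[str]
    freq: dict[str, int]
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be distinct")
        if set(self.freq) != set(self.labels):
            raise ValueError("freq keys must equal labels")
        for canon in self.merge_map.values():
            if canon not in self.freq:
                raise ValueError(f"merge_map target {canon!r} not in labels")

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def canonical(self, raw: str) -> str | None:
        canon = self.merge_map.get(raw, raw)
        return canon if canon in self.freq else None

    # -- serialisation: two-column label/frequency table + merge map ------

    def save(self, labels_path: str | Path, merge_path: str | Path | None = None) -> None:
        with Path(labels_path).open("w", encoding="utf-8") as fh:
            fh.write("label\tfrequency\n")
            for lab in self.labels:
                fh.write(f"{lab}\t{self.freq[lab]}\n")
        if merge_path is not None:
            with Path(merge_path).open("w", encoding="utf-8") as fh:
                fh.write("raw\tcanonical\n")
                for raw in sorted(self.merge_map):
                    fh.write(f"{raw}\t{self.merge_map[raw]}\n")

    @classmethod
    def load(cls, labels_path: str | Path, merge_path: str | Path | None = None) -> "LabelSpace":
        labels: list[str] = []
        freq: dict[str, int] = {}
        with Path(labels_path).open("r", encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                lab, n = line.rstrip("\n").split("\t")
                labels.append(lab)
                freq[lab] = int(n)
        merge_map: dict[str, str] = {}
        if merge_path is not None:
            with Path(merge_path).open("r", encoding="utf-8") as fh:
                next(fh)
                for line in fh:
                    raw, canon = line.rstrip("\n").split("\t")
                    merge_map[raw] = canon
        return cls(labels=labels, freq=freq, merge_map=merge_map)


def _space_order(freq: Mapping[str, int]) -> list[str]:
    return sorted(freq, key=lambda lab: (-freq[lab], lab))


def build_label_space(corpus: Iterable[EMRecord]) -> LabelSpace:
    """Label space from raw record labels, without any merging."""
    freq: Counter[str] = Counter()
    for rec in corpus:
        freq.update(rec.raw_labels)
    return LabelSpace(labels=_space_order(freq), freq=dict(freq), merge_map={})


def label_matrix(corpus: Sequence[EMRecord], space: LabelSpace) -> np.ndarray:
    """Binary p x Q matrix of record labels in ``space`` column order."""
    idx = space.index()
    Y = np.zeros((len(corpus), len(space.labels)), dtype=np.int8)
    for i, rec in enumerate(corpus):
        for raw in rec.raw_labels:
            canon = space.canonical(raw)
            if canon is not None:
                Y[i, idx[canon]] = 1
    return Y


# ---------------------------------------------------------------------------
# record cleaning
# ---------------------------------------------------------------------------


def _record_key(rec: EMRecord) -> tuple:
    return (
        rec.record_id,
        tuple(tuple(rec.sections[k]) for k in SECTION_KEYS),
        frozenset(rec.raw_labels),
        rec.record_time,
    )


def deduplicate_first_course(
    records: Sequence[EMRecord],
    reference_times: Mapping[str, float] | None = None,
) -> list[EMRecord]:
    """Clean a raw record stream down to one first-course record per id.

    Exact duplicates are dropped; records with no first-course content
    (all sections empty) are dropped; records whose time precedes their
    reference (admission) time are dropped as temporally inconsistent;
    among the survivors sharing a record id, the one with the most
    non-empty sections wins, then the latest record_time.
    """
    seen: set = set()
    unique: list[EMRecord] = []
    for rec in records:
        key = _record_key(rec)
        if key in seen:
            continue
        seen.add(key)
        unique.append(rec)

    eligible: list[EMRecord] = []
    for rec in unique:
        if rec.n_nonempty_sections() == 0:
            continue
        if (
            reference_times is not None
            and rec.record_id in reference_times
            and rec.record_time is not None
            and rec.record_time < reference_times[rec.record_id]
        ):
            continue
        eligible.append(rec)

    best: dict[str, EMRecord] = {}
    order: list[str] = []
    for rec in eligible:
        rid = rec.record_id
        if rid not in best:
            best[rid] = rec
            order.append(rid)
            continue
        cur = best[rid]
        new_rank = (rec.n_nonempty_sections(), rec.record_time or float("-inf"))
        cur_rank = (cur.n_nonempty_sections(), cur.record_time or float("-inf"))
        if new_rank > cur_rank:
            best[rid] = rec
    return [best[rid] for rid in order]


def split_sections(
    raw_text: str,
    header_patterns: Sequence[tuple[str, str]],
) -> dict[str, str]:
    """Assign text between matched headings to the named sections.

    ``header_patterns`` is an ordered list of ``(regex, section_key)``
    pairs.  Assignment follows the order the headings occur in the text;
    unmatched leading text goes to chief_complaints; sections whose
    heading is absent come back empty.
    """
    matches: list[tuple[int, int, str]] = []
    for pattern, key in header_patterns:
        if key not in SECTION_KEYS:
            raise ValueError(f"unknown section key {key!r}")
        for m in re.finditer(pattern, raw_text):
            matches.append((m.start(), m.end(), key))
    if not matches:
        raise StructureError("no section heading matched the text")
    matches.sort()

    sections: dict[str, str] = {key: "" for key in SECTION_KEYS}
    lead = raw_text[: matches[0][0]].strip()
    if lead:
        sections["chief_complaints"] = lead
    for i, (_, end, key) in enumerate(matches):
        nxt = matches[i + 1][0] if i + 1 < len(matches) else len(raw_text)
        chunk = raw_text[end:nxt].strip()
        if sections[key]:
            sections[key] = (sections[key] + " " + chunk).strip()
        else:
            sections[key] = chunk
    return sections


# ---------------------------------------------------------------------------
# tokenisation
# ---------------------------------------------------------------------------

_DELIMS = set(" \t\n\r\f\v,.;:!?()[]{}\"'、，。；：！？")


def tokenize(text: str, term_dictionary: Iterable[str] = ()) -> list[str]:
    """Greedy longest-match tokeniser with whitespace/punctuation fallback.

    At every position the longest dictionary term anchored there wins
    (terms may span spaces); outside dictionary matches, maximal runs of
    non-delimiter characters become tokens.  Deterministic.
    """
    by_first: dict[str, list[str]] = {}
    for term in term_dictionary:
        if term:
            by_first.setdefault(term[0], []).append(term)
    for terms in by_first.values():
        terms.sort(key=len, reverse=True)

    tokens: list[str] = []
    i, n = 0, len(text)
    buf: list[str] = []

    def flush() -> None:
        if buf:
            tokens.append("".join(buf))
            buf.clear()

    while i < n:
        ch = text[i]
        matched = None
        for term in by_first.get(ch, ()):
            if text.startswith(term, i):
                matched = term
                break
        if matched is not None:
            flush()
            tokens.append(matched)
            i += len(matched)
            continue
        if ch in _DELIMS:
            flush()
        else:
            buf.append(ch)
        i += 1
    flush()
    return tokens


# ---------------------------------------------------------------------------
# label standardisation
# ---------------------------------------------------------------------------

#: gestational-age and gravida/para diagnoses are computed quantities,
#: not classes
DEFAULT_EXCLUSION_PATTERNS: tuple[str, ...] = (
    r"pregnan\w*\s*\d+\s*(?:\+\s*\d+\s*)?weeks?",
    r"\d+\s*\+\s*\d+\s*weeks?",
    r"pregnan\w*\s*\d+\W*(?:production|para|birth)\w*\s*\d+",
)


def exclude_calculated_labels(
    raw_labels: Iterable[str],
    exclusion_patterns: Iterable[str] = DEFAULT_EXCLUSION_PATTERNS,
) -> set[str]:
    """Drop labels that are calculation results rather than diagnoses."""
    compiled = [re.compile(p, re.IGNORECASE) for p in exclusion_patterns]
    return {
        lab for lab in raw_labels if not any(p.search(lab) for p in compiled)
    }


def _tf_vector(label: str) -> Counter:
    return Counter(tokenize(label))


Vectorizer = Callable[[str], Mapping[str, float]]


def label_similarity(a: str, b: str, vectorizer: Vectorizer = _tf_vector) -> float:
    """Cosine similarity of two labels' semantic vectors, in [0, 1].

    The default vectorizer is a term-frequency vector over the label's
    tokenised components.  A zero vector on either side yields 0 with a
    warning.
    """
    va, vb = vectorizer(a), vectorizer(b)
    na = np.sqrt(sum(x * x for x in va.values()))
    nb = np.sqrt(sum(x * x for x in vb.values()))
    if na == 0.0 or nb == 0.0:
        warnings.warn(f"zero semantic vector for {a!r} or {b!r}; similarity set to 0")
        return 0.0
    dot = sum(va[t] * vb.get(t, 0.0) for t in va)
    return float(dot / (na * nb))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_labels(
    raw_labels: Iterable[str] | Mapping[str, int],
    threshold: float = 0.8,
    vectorizer: Vectorizer = _tf_vector,
) -> LabelSpace:
    """Merge synonymous labels by single-linkage similarity clustering.

    ``raw_labels`` is either an iterable of label occurrences (with
    multiplicity) or a label -> frequency mapping.  Labels whose pairwise
    similarity reaches ``threshold`` end up in one cluster; the cluster's
    most frequent member (ties: lexicographically first) becomes
    canonical, and frequencies are summed into it.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(raw_labels, Mapping):
        freq = dict(raw_labels)
    else:
        freq = dict(Counter(raw_labels))
    names = sorted(freq)
    uf = _UnionFind(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if label_similarity(names[i], names[j], vectorizer) >= threshold:
                uf.union(i, j)

    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        clusters.setdefault(uf.find(i), []).append(name)

    merge_map: dict[str, str] = {}
    merged_freq: dict[str, int] = {}
    for members in clusters.values():
        canon = min(members, key=lambda lab: (-freq[lab], lab))
        total = sum(freq[m] for m in members)
        merged_freq[canon] = total
        for m in members:
            merge_map[m] = canon
    return LabelSpace(labels=_space_order(merged_freq), freq=merged_freq, merge_map=merge_map)


def filter_labels_by_frequency(
    Y: np.ndarray,
    space: LabelSpace,
    min_keep_freq: int,
) -> tuple[np.ndarray, LabelSpace, np.ndarray]:
    """Drop labels below a corpus-frequency floor and emptied instances.

    Returns ``(reduced matrix, reduced space, dropped row indices)``.
    Frequencies are the column sums of ``Y``.  Raises if no label
    survives.
    """
    if min_keep_freq < 1:
        raise ValueError("min_keep_freq must be >= 1")
    Y = np.asarray(Y)
    col_freq = Y.sum(axis=0)
    keep_cols = np.flatnonzero(col_freq >= min_keep_freq)
    if keep_cols.size == 0:
        raise EmptyLabelSpaceError(
            f"no label has frequency >= {min_keep_freq}"
        )
    kept_labels = [space.labels[j] for j in keep_cols]
    reduced = Y[:, keep_cols]
    dropped_rows = np.flatnonzero(reduced.sum(axis=1) == 0)
    keep_rows = np.flatnonzero(reduced.sum(axis=1) > 0)
    reduced = reduced[keep_rows]
    kept_set = set(kept_labels)
    new_freq = {lab: int(f) for lab, f in zip(kept_labels, col_freq[keep_cols])}
    new_map = {raw: c for raw, c in space.merge_map.items() if c in kept_set}
    new_space = LabelSpace(labels=kept_labels, freq=new_freq, merge_map=new_map)
    return reduced, new_space, dropped_rows
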