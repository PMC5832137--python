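"""Core record container and JSON-lines corpus I/O.

A corpus is a list of first-course records, each carrying four tokenised
text sections (chief complaints, physical examination, obstetric
examination, auxiliary examinations) and the set of admitting-diagnosis
labels attached to the record.  On disk a corpus is JSON-lines: one object
per record with fields ``id``, the four section keys (token lists) and
``diagnoses`` (label list).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

SECTION_KEYS: tuple[str, ...] = (
    "chief_complaints",
    "physical_exam",
    "obstetric_exam",
    "auxiliary_exam",
)


class CorpusFormatError(ValueError):
    """Raised when a serialized corpus line cannot be parsed."""


@dataclass
class EMRecord:
    """One first-course record: four token-sequence sections plus labels."""

    record_id: str
    sections: dict[str, list[str]]
    raw_labels: set[str] = field(default_factory=set)
    record_time: float | None = None

    def __post_init__(self) -> None:
        for key in SECTION_KEYS:
            self.sections.setdefault(key, [])
        self.raw_labels = set(self.raw_labels)

    def tokens(self) -> list[str]:
        """All section tokens concatenated in canonical section order."""
        out: list[str] = []
        for key in SECTION_KEYS:
            out.extend(self.sections[key])
        return out

    def n_nonempty_sections(self) -> int:
        return sum(1 for key in SECTION_KEYS if self.sections[key])


def write_corpus(corpus: Iterable[EMRecord], path: str | Path) -> None:
    """Write a corpus as JSON-lines (one record object per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            obj: dict = {"id": rec.record_id}
            for key in SECTION_KEYS:
                obj[key] = list(rec.sections[key])
            obj["diagnoses"] = sorted(rec.raw_labels)
            if rec.record_time is not None:
                obj["record_time"] = rec.record_time
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=False))
            fh.write("\n")


def read_corpus(path: str | Path) -> list[EMRecord]:
    """Read a JSON-lines corpus; malformed lines raise with the line number."""
    path = Path(path)
    corpus: list[EMRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            if not isinstance(obj, dict) or "id" not in obj:
                raise CorpusFormatError(f"line {lineno}: record object with 'id' expected")
            sections: dict[str, list[str]] = {}
            for key in SECTION_KEYS:
                if key not in obj:
                    raise CorpusFormatError(f"line {lineno}: missing section '{key}'")
                sections[key] = [str(t) for t in obj[key]]
            corpus.append(
                EMRecord(
                    record_id=str(obj["id"]),
                    sections=sections,
                    raw_labels=set(obj.get("diagnoses", [])),
                    record_time=obj.get("record_time"),
                )
            )
    return corpus


def as_documents(corpus: Iterable[EMRecord]) -> list[list[str]]:
    """One token list per record (sections concatenated)."""
    return [rec.tokens() for rec in corpus]
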