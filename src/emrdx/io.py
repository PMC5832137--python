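"""Serialisation helpers: models, feature matrices and predictions."""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
import pandas as pd

FORMAT_VERSION = 1


def save_model(model, path: str | Path, config: dict | None = None) -> None:
    """Persist a fitted model in a versioned container with its config."""
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": type(model).__name__,
        "config": config or {},
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; returns (model, config)."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model container version {version!r}")
    return payload["model"], payload["config"]


def write_features(path: str | Path, X: np.ndarray, names: list[str]) -> None:
    """Delimited feature matrix with a header row of feature names."""
    pd.DataFrame(np.asarray(X), columns=names).to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_predictions(
    path: str | Path,
    instance_ids: list[str],
    scores: np.ndarray,
    bipartition: np.ndarray,
    labels: list[str],
) -> None:
    """Score and bipartition matrices keyed by instance id."""
    frame = pd.DataFrame(np.asarray(scores), columns=[f"score:{l}" for l in labels])
    bip = pd.DataFrame(np.asarray(bipartition), columns=[f"pred:{l}" for l in labels])
    out = pd.concat([pd.Series(instance_ids, name="id"), frame, bip], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_embeddings(path: str | Path, vocab: list[str], vectors: np.ndarray) -> None:
    """word2vec text format: first line "W T", then word + T floats."""
    vectors = np.asarray(vectors)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{vectors.shape[0]} {vectors.shape[1]}\n")
        for word, vec in zip(vocab, vectors):
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    with Path(path).open("r", encoding="utf-8") as fh:
        W, T = (int(x) for x in fh.readline().split())
        vocab, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vocab.append(parts[0])
            rows.append([float(x) for x in parts[1 : T + 1]])
    vectors = np.asarray(rows)
    if vectors.shape != (W, T):
        raise ValueError("embedding table shape does not match its header")
    return vocab, vectors
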