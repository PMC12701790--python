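"""Reading feature tables and writing scores, tensors and previews.

Feature tables are CSV/TSV with a header row and a ``label`` column, or
sparse libsvm-style text (``label idx:value ...``, 1-based indices).
Score matrices round-trip through CSV with a ``sample_id`` column and one
column per class.  Encoded tensors persist as ``.npz`` with a JSON
metadata sidecar; PNG previews scale each channel to 0-255.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.datasets import load_svmlight_file

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_scores",
    "read_scores",
    "save_tensors",
    "tensor_to_png",
]


def read_feature_table(path, fmt: str | None = None):
    """Load a labeled feature table; returns (X, y, feature_ids).

    ``fmt`` is 'csv', 'tsv' or 'libsvm'; inferred from the suffix when
    omitted.  Ragged rows, non-numeric features and a missing label
    column are format errors naming the offending location.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".svm": "libsvm", ".libsvm": "libsvm"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt == "libsvm":
        X, y = load_svmlight_file(str(path))
        X = np.asarray(X.todense())
        return X, y, [f"f{i}" for i in range(X.shape[1])]

    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column (columns: {list(df.columns)[:8]}...)")
    y = df["label"].to_numpy()
    feats = df.drop(columns=["label"])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
        raise ValueError(f"{path}: non-numeric feature columns {bad}") from exc
    if not np.all(np.isfinite(X)):
        rows = np.flatnonzero(~np.isfinite(X).all(axis=1))
        raise ValueError(f"{path}: non-finite values at data rows {rows[:10].tolist()}")
    return X, y, list(feats.columns)


def write_feature_table(path, X, y, feature_ids=None):
    feature_ids = feature_ids or [f"f{i}" for i in range(np.shape(X)[1])]
    df = pd.DataFrame(np.asarray(X), columns=feature_ids)
    df.insert(0, "label", np.asarray(y))
    df.to_csv(path, index=False)


def write_scores(path, scores, classes, sample_ids=None):
    scores = np.asarray(scores, dtype=float)
    ids = sample_ids if sample_ids is not None else np.arange(scores.shape[0])
    df = pd.DataFrame(scores, columns=[str(c) for c in np.asarray(classes)])
    df.insert(0, "sample_id", ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_scores(path):
    """Returns (scores, classes, sample_ids)."""
    df = pd.read_csv(path)
    ids = df["sample_id"].to_numpy()
    cols = [c for c in df.columns if c != "sample_id"]
    return df[cols].to_numpy(dtype=float), cols, ids


def save_tensors(path, tensors: np.ndarray, metadata: dict):
    """Persist an (n, H, W, 3) batch plus JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, tensors=np.asarray(tensors))
    side = path.with_suffix(".json")
    side.write_text(json.dumps(metadata, indent=2, default=str))


def tensor_to_png(t: np.ndarray, path):
    """Write an H x W x 3 tensor as a PNG, each channel scaled to 0-255.

    Row 0 is time 0 at the top; frequency bin 0 (or scale 0 / grid row 0)
    at the left.
    """
    t = np.asarray(t, dtype=float)
    img = np.zeros_like(t)
    for c in range(t.shape[2]):
        ch = t[:, :, c]
        rng = ch.max() - ch.min()
        if rng > 0:
            img[:, :, c] = (ch - ch.min()) / rng * 255
    Image.fromarray(img.astype(np.uint8)).save(path)
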