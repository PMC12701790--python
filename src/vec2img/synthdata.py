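"""Synthetic labeled feature-vector datasets with known class structure.

Two generative modes:

``spectral``
    Class ``c`` vectors are unit-amplitude sinusoids at frequency bin
    ``class_freqs[c]`` with a uniform random phase, plus i.i.d. Gaussian
    noise.  Classes differ only in spectral content, so time-frequency
    encodings are discriminative by construction and a
    periodogram-peak classifier is a closed-form oracle.

``mean_shift``
    Standard-normal vectors; class ``c`` adds ``c * effect_size`` to a
    random ``shift_fraction`` subset of features.  A classical mean-shift
    problem where an RBF SVM is a strong reference.

Generation is a pure function of the spec (numpy ``default_rng``
Philox-free PCG64, fixed across platforms).  The default world: two
classes, 200 samples/class, length 64, bins (5, 12), noise sd 0.5 —
small enough for one CPU, matching the shorter of the real feature-vector
regimes the encoders target (hundreds to thousands of features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SynthSpec", "Dataset", "generate", "periodogram_oracle", "fixture_tables"]


@dataclass(frozen=True)
class SynthSpec:
    n_per_class: int = 200
    length: int = 64
    mode: str = "spectral"
    class_freqs: tuple[int, ...] = (5, 12)
    effect_size: float = 1.0
    shift_fraction: float = 0.2
    n_classes: int = 2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.length < 16:
            raise ValueError(f"length must be >= 16, got {self.length}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if self.mode not in ("spectral", "mean_shift"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "spectral":
            freqs = self.class_freqs
            if len(set(freqs)) != len(freqs):
                raise ValueError("class frequency bins must be distinct")
            if any(f <= 0 or f >= self.length / 2 for f in freqs):
                raise ValueError("class frequency bins must lie in (0, length/2)")

    @property
    def n_classes_effective(self) -> int:
        return len(self.class_freqs) if self.mode == "spectral" else self.n_classes


@dataclass
class Dataset:
    """Feature table with labels and a stratified train/test split."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]


def _make_class_block(spec: SynthSpec, c: int, n: int, rng, shifted):
    L = spec.length
    if spec.mode == "spectral":
        phases = rng.uniform(0, 2 * np.pi, size=n)
        t = np.arange(L)
        X = np.sin(2 * np.pi * spec.class_freqs[c] * t[None, :] / L + phases[:, None])
        X += rng.normal(0, spec.noise_sd, size=(n, L))
    else:
        X = rng.normal(0, 1, size=(n, L))
        X[:, shifted] += c * spec.effect_size
    return X


def generate(spec: SynthSpec) -> Dataset:
    """Generate a dataset with a stratified 50/50 train/test split."""
    rng = np.random.default_rng(spec.seed)
    # one shifted-feature subset shared by all classes (mean_shift mode)
    n_shift = max(1, int(round(spec.shift_fraction * spec.length)))
    shifted = rng.choice(spec.length, size=n_shift, replace=False)
    blocks, labels = [], []
    for c in range(spec.n_classes_effective):
        blocks.append(_make_class_block(spec, c, spec.n_per_class, rng, shifted))
        labels.append(np.full(spec.n_per_class, c))
    X = np.vstack(blocks)
    y = np.concatenate(labels)
    # stratified 50/50 split, seeded
    train_idx, test_idx = [], []
    for c in range(spec.n_classes_effective):
        idx = rng.permutation(np.flatnonzero(y == c))
        half = idx.size // 2
        train_idx.append(idx[:half])
        test_idx.append(idx[half:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    ids = [f"f{i}" for i in range(spec.length)]
    return Dataset(X[train_idx], y[train_idx], X[test_idx], y[test_idx], ids)


def periodogram_oracle(X, class_freqs) -> np.ndarray:
    """Classify by nearest periodogram peak — the spectral-mode oracle."""
    X = np.asarray(X, dtype=float)
    spec = np.abs(np.fft.rfft(X - X.mean(axis=1, keepdims=True), axis=1)) ** 2
    peak = np.argmax(spec[:, 1:], axis=1) + 1
    freqs = np.asarray(class_freqs)
    return np.argmin(np.abs(peak[:, None] - freqs[None, :]), axis=1)


def _to_frame(X, y, feature_ids) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=feature_ids)
    df.insert(0, "label", y)
    return df


def dataset_to_frames(ds: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    return _to_frame(ds.X_train, ds.y_train, ds.feature_ids), _to_frame(
        ds.X_test, ds.y_test, ds.feature_ids
    )


def fixture_tables(outdir) -> dict[str, Path]:
    """Write small versioned CSV fixtures for tests and docs.

    ``spectral_small``: 2-class spectral table, 40 train + 40 test rows,
    L = 64.  ``long_vector``: L = 256 table (24 rows) exercising quadrant
    composition.  Returns name -> path of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    small = generate(SynthSpec(n_per_class=40, length=64, noise_sd=0.5, seed=7))
    train, test = dataset_to_frames(small)
    for name, df in (("spectral_small_train", train), ("spectral_small_test", test)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p

    long_ds = generate(SynthSpec(n_per_class=12, length=256, class_freqs=(9, 30),
                                 noise_sd=0.5, seed=11))
    frame = _to_frame(
        np.vstack([long_ds.X_train, long_ds.X_test]),
        np.concatenate([long_ds.y_train, long_ds.y_test]),
        long_ds.feature_ids,
    )
    p = outdir / "long_vector.csv"
    frame.to_csv(p, index=False, float_format="%.6g")
    paths["long_vector"] = p
    return paths
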