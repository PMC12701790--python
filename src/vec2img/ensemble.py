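"""Ensembles of image classifiers over encoded feature vectors.

Each ensemble member is an independent pipeline

    permute features -> (optional 0-255 train-min/max scaling) ->
    encode to H x W x 3 -> train a backbone for a fixed number of epochs,

with its own seed driving the feature permutation and the encoder's
window draws.  The state kept per member is the epoch whose training-set
metric was highest (ties -> earliest epoch), not the final epoch.
Ensemble scores are the unweighted mean of the member class-probability
matrices (the mean rule).

The backbone contract is minimal — ``fit(images, y)`` with an epoch loop
that records ``trace_`` and restores the best snapshot, plus
``predict_proba(images)`` — so GPU backbones can be plugged in.  The
in-tree backbone is a small fully-connected net (sklearn MLP, adam or
sgd+momentum, learning rate 0.001, batch size 30) over an average-pooled,
flattened image, which is enough for desk-scale work on one CPU.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .baselines import auc_score
from .encoders import FeaturePermuter, MinMax255Scaler, WignerEncoder

__all__ = [
    "SmallNetBackbone",
    "EnsembleImageClassifier",
    "select_best_epoch",
    "ensemble_predict",
    "MemberDidNotConverge",
]


class MemberDidNotConverge(RuntimeError):
    """Raised by a backbone whose training loss became non-finite."""


def select_best_epoch(trace) -> int:
    """Index of the epoch maximizing the training metric, earliest on ties."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty epoch trace")
    return int(np.argmax(trace))  # np.argmax returns the first maximum


def _avg_pool(images: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool H and W by ``factor`` (trailing remainder cropped)."""
    if factor <= 1:
        return images
    n, h, w, c = images.shape
    h2, w2 = h // factor, w // factor
    if h2 < 1 or w2 < 1:
        return images
    trimmed = images[:, : h2 * factor, : w2 * factor, :]
    return trimmed.reshape(n, h2, factor, w2, factor, c).mean(axis=(2, 4))


class SmallNetBackbone(BaseEstimator, ClassifierMixin):
    """Small fully-connected net over pooled, flattened image tensors.

    Trains for ``epochs`` passes (one sklearn-MLP iteration each) and
    keeps the weights of the epoch with the best training-set metric.
    ``selection_metric`` is 'accuracy' or 'auc' (training AUC of the
    positive-class score; 2-class only).

    Inputs are standardized by the per-pixel training mean/scale so the
    0-255 encoding convention does not destabilize the optimizer.
    """

    def __init__(self, hidden_layer_sizes=(64,), trainer="adam", learning_rate=0.001,
                 batch_size=30, epochs=30, pool=4, selection_metric="accuracy",
                 random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.trainer = trainer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.pool = pool
        self.selection_metric = selection_metric
        self.random_state = random_state

    def _flatten(self, images):
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError(f"expected (n, H, W, 3) image batch, got shape {images.shape}")
        pooled = _avg_pool(images, self.pool)
        return pooled.reshape(pooled.shape[0], -1)

    def _metric(self, flat, y) -> float:
        proba = self._mlp.predict_proba(flat)
        if self.selection_metric == "auc":
            if len(self._mlp.classes_) != 2:
                raise ValueError("selection_metric='auc' needs exactly 2 classes")
            return auc_score(y == self._mlp.classes_[1], proba[:, 1])
        return float(np.mean(self._mlp.classes_[np.argmax(proba, axis=1)] == y))

    def fit(self, images, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training partition must contain at least 2 classes")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        flat = self._flatten(images)
        self._mean = flat.mean(axis=0)
        self._scale = flat.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        flat = (flat - self._mean) / self._scale

        solver = {"adam": "adam", "sgd_momentum": "sgd"}[self.trainer]
        self._mlp = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            solver=solver,
            momentum=0.9,
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, flat.shape[0]),
            max_iter=1,
            warm_start=True,
            random_state=self.random_state,
            shuffle=True,
        )
        trace = []
        snapshots = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(self.epochs):
                self._mlp.fit(flat, y)
                if not np.isfinite(self._mlp.loss_):
                    raise MemberDidNotConverge(f"loss became {self._mlp.loss_!r}")
                trace.append(self._metric(flat, y))
                snapshots.append(
                    (copy.deepcopy(self._mlp.coefs_), copy.deepcopy(self._mlp.intercepts_))
                )
        self.trace_ = np.asarray(trace)
        self.best_epoch_ = select_best_epoch(self.trace_)
        self._mlp.coefs_, self._mlp.intercepts_ = snapshots[self.best_epoch_]
        self.classes_ = self._mlp.classes_
        return self

    def predict_proba(self, images):
        check_is_fitted(self, "trace_")
        flat = (self._flatten(images) - self._mean) / self._scale
        return self._mlp.predict_proba(flat)

    def predict(self, images):
        return self.classes_[np.argmax(self.predict_proba(images), axis=1)]


def ensemble_predict(members, images_per_member) -> np.ndarray:
    """Mean-rule score matrix over surviving members.

    ``images_per_member`` holds each member's already-encoded view of the
    same samples (members see different permutations/encodings).
    """
    if len(members) == 0:
        raise ValueError("no surviving ensemble members")
    scores = [m.predict_proba(imgs) for m, imgs in zip(members, images_per_member)]
    return np.mean(scores, axis=0)


class EnsembleImageClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of permute -> scale -> encode -> backbone pipelines.

    Parameters
    ----------
    encoder : transformer template, cloned and reseeded per member
        (default: WignerEncoder).
    backbone : classifier template satisfying the backbone contract
        (default: SmallNetBackbone).
    n_members : ensemble size (the reference protocol uses 15; desk-scale
        runs use 3).
    normalize_0_255 : rescale features to the training [0, 255] range
        before encoding (the convention of the sgd/ResNet-style path; the
        adam/MobileNet-style path skips it for diversity).
    random_state : master seed; member seeds are spawned from it.

    Fitted attributes: ``members_`` (list of dicts with the fitted
    permuter/scaler/encoder/backbone and the member seed),
    ``dropped_members_`` (seeds of members whose training diverged),
    ``classes_``.
    """

    def __init__(self, encoder=None, backbone=None, n_members=15,
                 normalize_0_255=True, random_state=None):
        self.encoder = encoder
        self.backbone = backbone
        self.n_members = n_members
        self.normalize_0_255 = normalize_0_255
        self.random_state = random_state

    def _member_seeds(self):
        ss = np.random.SeedSequence(self.random_state)
        return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(self.n_members)]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training partition must contain at least 2 classes")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        self.classes_ = np.unique(y)
        encoder_template = self.encoder if self.encoder is not None else WignerEncoder()
        backbone_template = self.backbone if self.backbone is not None else SmallNetBackbone()
        self.members_ = []
        self.dropped_members_ = []
        for seed in self._member_seeds():
            permuter = FeaturePermuter(random_state=seed).fit(X)
            Xp = permuter.transform(X)
            scaler = None
            if self.normalize_0_255:
                scaler = MinMax255Scaler().fit(Xp)
                Xp = scaler.transform(Xp)
            encoder = clone(encoder_template)
            if "random_state" in encoder.get_params():
                encoder.set_params(random_state=seed)
            images = encoder.fit(Xp).transform(Xp)
            backbone = clone(backbone_template)
            if "random_state" in backbone.get_params():
                backbone.set_params(random_state=seed)
            try:
                backbone.fit(images, y)
            except MemberDidNotConverge as exc:
                warnings.warn(f"dropping member seed={seed}: {exc}", RuntimeWarning)
                self.dropped_members_.append(seed)
                continue
            self.members_.append(
                {"seed": seed, "permuter": permuter, "scaler": scaler,
                 "encoder": encoder, "backbone": backbone}
            )
        if not self.members_:
            raise RuntimeError("all ensemble members failed to converge")
        return self

    def _member_images(self, member, X):
        Xp = member["permuter"].transform(np.asarray(X, dtype=float))
        if member["scaler"] is not None:
            Xp = member["scaler"].transform(Xp)
        return member["encoder"].transform(Xp)

    def member_scores(self, X) -> list[np.ndarray]:
        """Per-member class-probability matrices for ``X``."""
        check_is_fitted(self, "members_")
        return [
            m["backbone"].predict_proba(self._member_images(m, X)) for m in self.members_
        ]

    def predict_proba(self, X):
        return np.mean(self.member_scores(X), axis=0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
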