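"""Optimized SVM reference classifier and evaluation metrics.

The SVM protocol: features min/max-scaled to [0, 1] with parameters from
the training partition only (no clipping), then an RBF SVM whose cost and
kernel width are chosen by grid search with 5-fold stratified
cross-validation internal to the training data, refit on the full
training partition.  Default grids follow libsvm practice
(C in 2^-5..2^15, gamma in 2^-15..2^3).  Ties prefer the smallest cost,
then the smallest width.

Metrics: AUC in the Mann-Whitney rank formulation (the probability a
random positive outscores a random negative, ties counted half) for
2-class problems, accuracy by argmax for multi-class, plus a stratified
k-fold protocol helper.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "auc_score",
    "accuracy_from_scores",
    "evaluate",
    "normalize_01",
    "MinMax01Scaler",
    "OptimizedSVC",
    "kfold_protocol",
]

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    ``y_true`` holds two classes (booleans or the larger label positive);
    ties in ``scores`` contribute 1/2 per tied positive-negative pair.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError(f"AUC needs exactly 2 classes, got {classes.size}")
    pos = y_true == classes[1]
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties exactly
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def accuracy_from_scores(scores, y_true, classes) -> float:
    """Accuracy of argmax predictions from a samples x classes score matrix."""
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes)
    pred = classes[np.argmax(scores, axis=1)]
    return float(np.mean(pred == np.asarray(y_true)))


def evaluate(scores, y_true, classes=None) -> dict:
    """AUC for 2-class problems, accuracy by argmax otherwise.

    ``scores`` is a samples x classes matrix; columns follow ``classes``
    (default: sorted unique labels).
    """
    y_true = np.asarray(y_true)
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (y_true.size, classes.size):
        raise ValueError(
            f"scores shape {scores.shape} does not match {y_true.size} samples x "
            f"{classes.size} classes"
        )
    out = {"accuracy": accuracy_from_scores(scores, y_true, classes)}
    if classes.size == 2:
        out["auc"] = auc_score(y_true == classes[1], scores[:, 1])
    return out


class MinMax01Scaler(BaseEstimator):
    """Train-only min/max scaling to [0, 1]; test values may leave the range."""

    def fit(self, X, y=None):
        self._scaler = MinMaxScaler(feature_range=(0.0, 1.0), clip=False)
        self._scaler.fit(np.asarray(X, dtype=float))
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        return self._scaler.transform(np.asarray(X, dtype=float))


def normalize_01(train_features, apply_to=None):
    """[0, 1] scaling with parameters from the training data only."""
    scaler = MinMax01Scaler().fit(train_features)
    return scaler.transform(train_features if apply_to is None else apply_to)


def _tie_break_refit(cv_results) -> int:
    """Best mean CV score; exact ties -> smallest C, then smallest gamma."""
    scores = np.asarray(cv_results["mean_test_score"])
    best = np.nanmax(scores)
    candidates = np.flatnonzero(scores == best)
    keys = [
        (float(cv_results["param_C"][i]), float(cv_results["param_gamma"][i]))
        for i in candidates
    ]
    return int(min(zip(keys, candidates))[1])


class OptimizedSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM with train-only [0,1] scaling and internal 5-fold grid search.

    The inner selection metric mirrors the outer one: ROC AUC for 2-class
    problems, accuracy otherwise.  Scores for fusion come from
    ``predict_proba`` (Platt estimates) by default; set
    ``score_kind='decision'`` for raw decision values (2-class).

    Fitted attributes: ``best_params_`` (always members of the declared
    grid), ``cv_results_``, ``classes_``.
    """

    def __init__(self, C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 inner_folds=5, kernel="rbf", score_kind="probability",
                 random_state=None):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.kernel = kernel
        self.score_kind = score_kind
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training partition must contain at least 2 classes")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if len(self.C_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")
        counts = np.bincount(np.searchsorted(self.classes_, y))
        if counts.min() < self.inner_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; cannot stratify "
                f"{self.inner_folds}-fold inner CV"
            )
        self._scaler = MinMax01Scaler().fit(X)
        Xs = self._scaler.transform(X)
        scoring = "roc_auc" if self.classes_.size == 2 else "accuracy"
        cv = StratifiedKFold(self.inner_folds, shuffle=True, random_state=self.random_state)
        with warnings.catch_warnings():
            # sklearn 1.9 deprecates probability=True; Platt scores are the
            # documented fusion currency here, so keep it until removal
            warnings.simplefilter("ignore", FutureWarning)
            search = GridSearchCV(
                SVC(kernel=self.kernel, probability=True, random_state=self.random_state),
                {"C": list(self.C_grid), "gamma": list(self.gamma_grid)},
                scoring=scoring,
                cv=cv,
                refit=_tie_break_refit,
                n_jobs=None,
            )
            search.fit(Xs, y)
        self._search = search
        self.best_params_ = search.best_params_
        self.cv_results_ = search.cv_results_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "best_params_")
        return self._search.predict_proba(self._scaler.transform(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        check_is_fitted(self, "best_params_")
        return self._search.decision_function(self._scaler.transform(np.asarray(X, dtype=float)))

    def scores(self, X) -> np.ndarray:
        """samples x classes score matrix for fusion."""
        if self.score_kind == "decision":
            d = self.decision_function(X)
            if d.ndim == 1:  # 2-class: symmetric two-column matrix
                return np.column_stack([-d, d])
            return d
        return self.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.scores(X), axis=1)]


def kfold_protocol(estimator, X, y, n_folds: int = 10, random_state=None) -> dict:
    """Stratified k-fold testing protocol; pools out-of-fold scores.

    Returns per-fold metric dicts plus pooled scores/labels and the pooled
    metric, matching the cross-validation protocol used for multi-class
    barcoding-style evaluations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=random_state)
    fold_metrics = []
    pooled_scores = np.empty((y.size, classes.size))
    for train_idx, test_idx in skf.split(X, y):
        model = clone(estimator).fit(X[train_idx], y[train_idx])
        s = model.predict_proba(X[test_idx]) if hasattr(model, "predict_proba") else model.scores(X[test_idx])
        pooled_scores[test_idx] = s
        fold_metrics.append(evaluate(s, y[test_idx], classes))
    return {
        "folds": fold_metrics,
        "scores": pooled_scores,
        "labels": y,
        "pooled": evaluate(pooled_scores, y, classes),
    }
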