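"""Score-level fusion: mean rule and z-normalized weighted mean rule.

A score matrix is a samples x classes array of classifier outputs.  The
mean rule averages aligned matrices; the weighted rule computes
``sum_i w_i * S_i``, optionally z-normalizing each component to mean 0 /
sd 1 (over all entries) first so sources on different scales are
commensurable.  Ranking metrics (AUC, argmax accuracy) are invariant to
positive rescaling of the fused output, so weights matter only through
their ratios.

Rules can be written in a mini-grammar, e.g. ``"2*svm+1*cnne"``: a
``+``-separated list of ``weight*name`` terms, weight defaulting to 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["FusionRule", "z_normalize_scores", "fuse", "mean_rule", "parse_rule"]


def z_normalize_scores(S, per_class: bool = False) -> np.ndarray:
    """Affine-transform a score matrix to mean 0, standard deviation 1.

    Moments are taken over all entries (``per_class=True`` normalizes each
    column separately).  A constant matrix/column has no defined scale and
    raises.
    """
    S = np.asarray(S, dtype=float)
    axis = 0 if per_class else None
    sd = S.std(axis=axis)
    if np.any(sd == 0):
        raise ValueError("cannot z-normalize a constant score matrix")
    return (S - S.mean(axis=axis)) / sd


@dataclass(frozen=True)
class FusionRule:
    """Weighted combination of named score sources.

    ``components`` pairs a source name with a nonnegative weight;
    ``normalize`` z-normalizes each component before the weighted sum
    (the convention for cross-family fusions such as weighted SVM+CNN;
    the plain mean rule over same-scale softmax ensembles skips it).
    """

    components: Sequence[tuple[str, float]]
    normalize: bool = True

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("fusion rule needs at least one component")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be nonnegative and not all zero")


def fuse(rule: FusionRule, scores: Mapping[str, np.ndarray]) -> np.ndarray:
    """Apply a fusion rule to named score matrices (all shape-aligned)."""
    mats = []
    shape = None
    for name, weight in rule.components:
        S = np.asarray(scores[name], dtype=float)
        if shape is None:
            shape = S.shape
        elif S.shape != shape:
            raise ValueError(f"score matrix {name!r} has shape {S.shape}, expected {shape}")
        if rule.normalize:
            S = z_normalize_scores(S)
        mats.append(weight * S)
    return np.sum(mats, axis=0)


def mean_rule(score_matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Plain (unnormalized, equal-weight) mean of score matrices."""
    named = {f"s{i}": S for i, S in enumerate(score_matrices)}
    rule = FusionRule([(k, 1.0) for k in named], normalize=False)
    return fuse(rule, named) / len(score_matrices)


_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\*)?([A-Za-z_][\w.-]*)$")


def parse_rule(text: str, normalize: bool = True) -> FusionRule:
    """Parse ``"2*svm+cnne"``-style rule text into a FusionRule."""
    components = []
    for raw in text.split("+"):
        m = _TERM.match(raw.strip())
        if m is None:
            raise ValueError(f"cannot parse fusion term {raw!r} (expected [w*]name)")
        weight = float(m.group(1)) if m.group(1) else 1.0
        components.append((m.group(2), weight))
    return FusionRule(components, normalize=normalize)
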