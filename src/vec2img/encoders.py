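"""Vector-to-image encoders: turn 1-D feature vectors into H x W x 3 tensors.

The headline encoder is the Wigner encoder: each channel ``i`` of the
output is the smoothed Wigner-Ville distribution of the vector with a
Kaiser window of size ``M_i`` used for both the time and the frequency
window.  The three sizes are drawn once per encoder instance as

    M1 ~ U(0.3 N, 0.5 N),  M2 ~ U(0.5 N, 0.7 N),  M3 ~ U(0.7 N, 0.9 N),

rounded to odd integers and sorted, so M1 <= M2 <= M3.  The random,
increasing sizes break the symmetry between ensemble members and are the
source of ensemble diversity.  Long vectors can instead be split into
four equal-length segments, each encoded independently, with the four
matrices tiled as quadrants of one composite image.

Baseline encoders: plain row-major reshape, a Morlet-scalogram CWT and a
tiled multilevel Daubechies DWT.  All encoders are deterministic given
(input, seed) and expose a scikit-learn transformer interface producing
``(n_samples, H, W, 3)`` arrays.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from . import _wavelets
from .tfcore import DEFAULT_BETA, WindowSpec, swvd, validate_signal

__all__ = [
    "sample_window_sizes",
    "encode_wigner",
    "quadrant_compose",
    "encode_reshape",
    "encode_cwt",
    "encode_dwt",
    "normalize_0_255",
    "permute_features",
    "resize_to_backbone",
    "WignerEncoder",
    "ReshapeEncoder",
    "CWTEncoder",
    "DWTEncoder",
    "MinMax255Scaler",
    "FeaturePermuter",
]

MIN_SEGMENT = 10

_WINDOW_RANGES = ((0.3, 0.5), (0.5, 0.7), (0.7, 0.9))


def _round_to_odd(v: float) -> int:
    m = int(2 * round((v - 1) / 2) + 1)
    return max(m, 1)


def sample_window_sizes(N: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Draw the (M1, M2, M3) Kaiser sizes for one Wigner encoding.

    Uniform on (0.3N, 0.5N), (0.5N, 0.7N), (0.7N, 0.9N), rounded to odd
    integers; the triple is sorted so M1 <= M2 <= M3 holds even when
    odd-rounding nudges adjacent draws across a range boundary.
    """
    if N < MIN_SEGMENT:
        raise ValueError(f"segment length {N} < {MIN_SEGMENT}: windows would collapse")
    sizes = sorted(_round_to_odd(rng.uniform(lo * N, hi * N)) for lo, hi in _WINDOW_RANGES)
    return tuple(sizes)


def encode_wigner(
    x,
    rng: np.random.Generator | None = None,
    window_sizes: tuple[int, int, int] | None = None,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """Encode one vector segment as an N x N x 3 Wigner-Ville tensor.

    Channel ``i`` is ``swvd(x, g=Kaiser(M_i), H=Kaiser(M_i))``; pass
    ``window_sizes`` to reuse a triple, or ``rng`` to sample one.
    """
    x = validate_signal(x, min_len=MIN_SEGMENT)
    N = x.shape[0]
    if window_sizes is None:
        if rng is None:
            raise ValueError("provide either window_sizes or rng")
        window_sizes = sample_window_sizes(N, rng)
    out = np.empty((N, N, 3))
    for i, M in enumerate(window_sizes):
        w = WindowSpec(int(M), beta)
        out[:, :, i] = swvd(x, w, w)
    return out


def quadrant_compose(
    x,
    rng: np.random.Generator | None = None,
    window_sizes=None,
    beta: float = DEFAULT_BETA,
    share_windows: bool = False,
) -> np.ndarray:
    """Encode a long vector as four Wigner quadrants of one composite image.

    The vector is zero-padded to a multiple of 4, split into four equal
    contiguous segments, each encoded independently (independent window
    triples by default; ``share_windows=True`` samples one triple for all
    four), and tiled in reading order: segment 1 top-left, 2 top-right,
    3 bottom-left, 4 bottom-right.  Output is (2 Ns) x (2 Ns) x 3.

    ``window_sizes`` may be a single triple (shared) or a list of four.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 4 * MIN_SEGMENT:
        raise ValueError(
            f"vector length {x.shape[0]} < {4 * MIN_SEGMENT}; encode directly with encode_wigner"
        )
    L = int(np.ceil(x.shape[0] / 4) * 4)
    xp = np.zeros(L)
    xp[: x.shape[0]] = x
    segments = xp.reshape(4, L // 4)
    ns = L // 4

    if window_sizes is not None:
        triples = (
            [tuple(window_sizes)] * 4
            if np.ndim(window_sizes) == 1
            else [tuple(t) for t in window_sizes]
        )
    elif share_windows:
        triples = [sample_window_sizes(ns, rng)] * 4
    else:
        triples = [sample_window_sizes(ns, rng) for _ in range(4)]

    out = np.empty((2 * ns, 2 * ns, 3))
    slots = ((slice(0, ns), slice(0, ns)), (slice(0, ns), slice(ns, None)),
             (slice(ns, None), slice(0, ns)), (slice(ns, None), slice(ns, None)))
    for seg, triple, (rs, cs) in zip(segments, triples, slots):
        out[rs, cs, :] = encode_wigner(seg, window_sizes=triple, beta=beta)
    return out


def encode_reshape(x) -> np.ndarray:
    """Zero-pad to the next perfect square, fill row-major, replicate to 3 channels."""
    x = validate_signal(x, min_len=4)
    s = int(np.ceil(np.sqrt(x.shape[0])))
    grid = np.zeros(s * s)
    grid[: x.shape[0]] = x
    return np.repeat(grid.reshape(s, s)[:, :, None], 3, axis=2)


#: Morlet center frequencies giving three distinct time/frequency trade-offs
CWT_W0 = (5.0, 6.0, 8.0)


def encode_cwt(x, w0s=CWT_W0) -> np.ndarray:
    """Morlet magnitude scalogram over L log-spaced scales -> L x L x 3.

    Rows are scales (coarse at the bottom), columns time; the three
    channels use three Morlet center frequencies ``w0``.
    """
    x = validate_signal(x, min_len=MIN_SEGMENT)
    L = x.shape[0]
    out = np.empty((L, L, 3))
    for i, w0 in enumerate(w0s):
        scales = _wavelets.morlet_scales(L, w0, L)
        out[:, :, i] = _wavelets.morlet_scalogram(x, scales, w0)
    return out


DWT_WAVELETS = ("haar", "db2", "db4")


def encode_dwt(x, wavelets=DWT_WAVELETS) -> np.ndarray:
    """Multilevel DWT coefficients tiled into a square grid, one wavelet per channel.

    The vector is zero-padded to the next power of two, decomposed to the
    maximum depth, and the concatenated ``[cA_L, cD_L, ..., cD_1]``
    coefficient vector is tiled row-major into an s x s grid (zero-padded).
    """
    x = validate_signal(x, min_len=16)
    P = 1 << int(np.ceil(np.log2(x.shape[0])))
    xp = np.zeros(P)
    xp[: x.shape[0]] = x
    s = int(np.ceil(np.sqrt(P)))
    out = np.zeros((s, s, 3))
    for i, wav in enumerate(wavelets):
        flat = np.concatenate(_wavelets.wavedec(xp, wav))
        grid = np.zeros(s * s)
        grid[: flat.size] = flat
        out[:, :, i] = grid.reshape(s, s)
    return out


def normalize_0_255(train_features, apply_to=None):
    """Per-feature affine map sending train-min -> 0 and train-max -> 255.

    Parameters come from the training partition only; applied unchanged to
    ``apply_to`` (default: the training data itself).  Out-of-range values
    are NOT clipped, so test features may fall outside [0, 255]; constant
    training columns map to 0.
    """
    scaler = MinMax255Scaler().fit(train_features)
    return scaler.transform(train_features if apply_to is None else apply_to)


class MinMax255Scaler(BaseEstimator, TransformerMixin):
    """Train-only min/max scaling to [0, 255], no clipping."""

    def fit(self, X, y=None):
        self._scaler = MinMaxScaler(feature_range=(0.0, 255.0), clip=False)
        self._scaler.fit(np.asarray(X, dtype=float))
        self.data_min_ = self._scaler.data_min_
        self.data_max_ = self._scaler.data_max_
        self.n_features_in_ = self._scaler.n_features_in_
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        return self._scaler.transform(np.asarray(X, dtype=float))


class FeaturePermuter(BaseEstimator, TransformerMixin):
    """One random permutation of the feature axis, shared across partitions.

    Drawn in ``fit`` from ``random_state`` and recorded in
    ``permutation_``; ``inverse_transform`` restores the original order.
    """

    def __init__(self, random_state=None):
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.permutation_ = rng.permutation(self.n_features_in_)
        return self

    def transform(self, X):
        check_is_fitted(self, "permutation_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return X[:, self.permutation_]

    def inverse_transform(self, X):
        check_is_fitted(self, "permutation_")
        inv = np.empty_like(self.permutation_)
        inv[self.permutation_] = np.arange(self.permutation_.size)
        return np.asarray(X)[:, inv]


def permute_features(X_train, X_test, seed):
    """Permute train and test features identically; returns (train, test, permutation)."""
    perm = FeaturePermuter(random_state=seed).fit(X_train)
    return perm.transform(X_train), perm.transform(X_test), perm.permutation_


def resize_to_backbone(t: np.ndarray, target_size: int | tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an H x W x C tensor to the backbone input size."""
    if np.isscalar(target_size):
        target_size = (int(target_size), int(target_size))
    if min(target_size) < 2:
        raise ValueError(f"degenerate target size {target_size}")
    t = np.asarray(t, dtype=float)
    if t.shape[:2] == tuple(target_size):
        return t.copy()
    return _sk_resize(
        t, (*target_size, t.shape[2]), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


class _ArrayEncoder(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing: encode each row to H x W x 3."""

    min_length = 4

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected 2-D (samples x features), got shape {X.shape}")
        if X.shape[1] < self.min_length:
            raise ValueError(f"need at least {self.min_length} features, got {X.shape[1]}")
        self.n_features_in_ = X.shape[1]
        self._fit_extra(X)
        return self

    def _fit_extra(self, X):
        pass

    def _encode_one(self, x) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        imgs = [self._encode_one(row) for row in X]
        out = np.stack(imgs)
        if self.target_size is not None:
            out = np.stack([resize_to_backbone(img, self.target_size) for img in out])
        return out

    def get_feature_names_out(self, input_features=None):  # pragma: no cover
        raise NotImplementedError("image tensors have no flat feature names")


class WignerEncoder(_ArrayEncoder):
    """Smoothed Wigner-Ville vector-to-image encoder.

    Window triples are drawn once in ``fit`` (``window_sizes_``); every
    transformed sample of one fitted instance shares them, so ensemble
    diversity comes from refitting with different seeds.  Vectors longer
    than ``quadrant_threshold`` are encoded as four quadrants.

    Parameters
    ----------
    beta : Kaiser shape parameter of all smoothing windows.
    quadrant_threshold : length above which quadrant composition is used,
        or None to always encode the whole vector directly.
    share_quadrant_windows : sample one triple for all four quadrants
        instead of four independent triples.
    target_size : optional (H, W) bilinear resize for a fixed-input backbone.
    random_state : seed for the window-size draws.
    """

    min_length = MIN_SEGMENT

    def __init__(self, beta=DEFAULT_BETA, quadrant_threshold=None,
                 share_quadrant_windows=False, target_size=None, random_state=None):
        self.beta = beta
        self.quadrant_threshold = quadrant_threshold
        self.share_quadrant_windows = share_quadrant_windows
        self.target_size = target_size
        self.random_state = random_state

    def _use_quadrants(self, L: int) -> bool:
        return self.quadrant_threshold is not None and L > self.quadrant_threshold

    def _fit_extra(self, X):
        rng = np.random.default_rng(self.random_state)
        L = self.n_features_in_
        if self._use_quadrants(L):
            ns = int(np.ceil(L / 4) * 4) // 4
            if ns < MIN_SEGMENT:
                raise ValueError(f"quadrant segments of length {ns} are below {MIN_SEGMENT}")
            if self.share_quadrant_windows:
                self.window_sizes_ = [sample_window_sizes(ns, rng)] * 4
            else:
                self.window_sizes_ = [sample_window_sizes(ns, rng) for _ in range(4)]
        else:
            self.window_sizes_ = sample_window_sizes(L, rng)

    def _encode_one(self, x):
        if self._use_quadrants(self.n_features_in_):
            return quadrant_compose(x, window_sizes=self.window_sizes_, beta=self.beta)
        return encode_wigner(x, window_sizes=self.window_sizes_, beta=self.beta)


class ReshapeEncoder(_ArrayEncoder):
    """Row-major reshape to the next perfect square, replicated to 3 channels."""

    def __init__(self, target_size=None):
        self.target_size = target_size

    def _encode_one(self, x):
        return encode_reshape(x)


class CWTEncoder(_ArrayEncoder):
    """Morlet scalogram encoder; channels use three center frequencies."""

    min_length = MIN_SEGMENT

    def __init__(self, w0s=CWT_W0, target_size=None):
        self.w0s = w0s
        self.target_size = target_size

    def _encode_one(self, x):
        return encode_cwt(x, self.w0s)


class DWTEncoder(_ArrayEncoder):
    """Tiled multilevel Daubechies DWT encoder; one wavelet family per channel."""

    min_length = 16

    def __init__(self, wavelets=DWT_WAVELETS, target_size=None):
        self.wavelets = wavelets
        self.target_size = target_size

    def _encode_one(self, x):
        return encode_dwt(x, self.wavelets)
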