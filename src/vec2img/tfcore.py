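"""Discrete Wigner-Ville and smoothed Wigner-Ville distributions.

The Wigner-Ville distribution (WVD) of a discrete signal ``x`` of length
``N`` is the DFT over lag of the instantaneous autocorrelation
``R(n, m) = x(n + m) * conj(x(n - m))``.  The symmetric integer-lag product
avoids half-sample interpolation at the cost of a *doubled-frequency*
convention: frequency bin ``k`` of the output corresponds to normalized
frequency ``k / (2N)`` cycles/sample, so a sinusoid at bin ``k0`` (frequency
``k0 / N``) concentrates at output bin ``2 * k0 (mod N)`` and, for real
input, at its mirror ``N - 2 * k0``.

The smoothed WVD (SWVD) convolves the lag products over time with a
unit-sum window ``g`` and tapers them over lag with a window ``H`` before
the lag DFT; the time smoothing suppresses the oscillatory cross terms
between signal components (including the interference between the positive
and negative spectral halves of a real signal) while the lag window trades
frequency resolution for further smoothing.  The SWVD returned here is the
point-wise absolute value, hence non-negative.

Axis convention of the returned ``N x N`` matrices: rows index time
``n = 0..N-1``, columns index frequency bins ``k = 0..N-1`` (normalized
frequency ``k / (2N)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, hilbert
from scipy.signal.windows import kaiser as _kaiser

__all__ = [
    "WindowSpec",
    "kaiser_window",
    "lag_product_array",
    "wvd_plain",
    "swvd",
    "bin_to_frequency",
]

#: relative tolerance above which a non-vanishing imaginary residue of the
#: lag DFT is treated as a programming error rather than rounding noise
IMAG_RTOL = 1e-9

DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class WindowSpec:
    """A Kaiser smoothing window: ``size`` taps with shape parameter ``beta``.

    ``beta = 0`` degenerates to the rectangular window.  Even sizes are
    promoted to the next odd integer so the window has a well-defined
    center tap.
    """

    size: int
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if int(self.size) != self.size or self.size < 1:
            raise ValueError(f"window size must be a positive integer, got {self.size!r}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"Kaiser beta must be a finite nonnegative real, got {self.beta!r}")

    @property
    def odd_size(self) -> int:
        n = int(self.size)
        return n if n % 2 == 1 else n + 1

    def taps(self) -> np.ndarray:
        return kaiser_window(self.odd_size, self.beta)


def kaiser_window(size: int, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Symmetric Kaiser window of ``size`` taps, peak 1 at the center."""
    if int(size) != size or size <= 0:
        raise ValueError(f"window size must be a positive integer, got {size!r}")
    if size == 1:
        return np.ones(1)
    return _kaiser(int(size), beta, sym=True)


def _as_window(w) -> WindowSpec:
    if isinstance(w, WindowSpec):
        return w
    if np.isscalar(w):
        return WindowSpec(int(w))
    size, beta = w
    return WindowSpec(int(size), float(beta))


def validate_signal(x, min_len: int = 2) -> np.ndarray:
    """Coerce to a 1-D float/complex array, rejecting NaN/inf and short input."""
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {arr.shape}")
    if arr.shape[0] < min_len:
        raise ValueError(f"signal must have at least {min_len} samples, got {arr.shape[0]}")
    if not np.iscomplexobj(arr):
        arr = arr.astype(float, copy=False)
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite values")
    return arr


def lag_product_array(x) -> np.ndarray:
    """Instantaneous autocorrelation ``R(n, m) = x(n+m) * conj(x(n-m))``.

    Returns an ``N x (2N-1)`` array whose column ``j`` holds lag
    ``m = j - (N - 1)``; indices outside ``0..N-1`` contribute zero
    (feature vectors are not periodic).
    """
    x = validate_signal(x)
    N = x.shape[0]
    n = np.arange(N)[:, None]
    m = np.arange(-(N - 1), N)[None, :]
    a = n + m
    b = n - m
    ok = (a >= 0) & (a < N) & (b >= 0) & (b < N)
    R = np.zeros((N, 2 * N - 1), dtype=complex if np.iscomplexobj(x) else float)
    R[ok] = x[a[ok]] * np.conj(x[b[ok]])
    return R


def _lag_dft(R: np.ndarray) -> np.ndarray:
    """DFT over the lag axis with kernel ``exp(-2j pi k m / N)``.

    Lags are folded modulo ``N`` (the kernel has period ``N`` in ``m``)
    so a single length-``N`` FFT per time row suffices.  The result of a
    Hermitian-in-lag input is real; a larger imaginary residue raises.
    """
    N = R.shape[0]
    m = np.arange(-(N - 1), N)
    folded = np.zeros((N, N), dtype=complex)
    np.add.at(folded, (slice(None), m % N), R)
    W = np.fft.fft(folded, axis=1)
    scale = np.abs(W).max()
    resid = np.abs(W.imag).max()
    if scale > 0 and resid > IMAG_RTOL * scale:
        raise ArithmeticError(
            f"imaginary residue {resid:.3e} exceeds {IMAG_RTOL:g} x max magnitude {scale:.3e}; "
            "lag products are not Hermitian in the lag"
        )
    return W.real


def wvd_plain(x, analytic: bool = False) -> np.ndarray:
    """Plain (unsmoothed) discrete Wigner-Ville distribution, ``N x N``.

    Real-valued but signed.  For a real multi-component signal the
    positive/negative spectral halves interfere near DC; pass
    ``analytic=True`` to compute the WVD of the analytic signal instead,
    which removes that interference (standard practice).
    """
    x = validate_signal(x)
    if analytic:
        x = hilbert(np.real(x))
    return _lag_dft(lag_product_array(x))


def swvd(x, g, H, analytic: bool = False) -> np.ndarray:
    """Smoothed Wigner-Ville distribution, point-wise absolute value.

    Parameters
    ----------
    x : array-like
        Real (or complex) signal of length N.
    g : WindowSpec, int or (size, beta)
        Time-smoothing window; convolved (unit-sum normalized) with the
        lag products along time.  Size must not exceed N.
    H : WindowSpec, int or (size, beta)
        Lag window implementing frequency smoothing; multiplies the lag
        axis, centered at lag 0.  Size must not exceed 2N - 1 (a
        rectangular H covering all 2N - 1 lags together with a size-1 g
        reduces the SWVD to ``|wvd_plain(x)|``).
    analytic : bool
        Apply the analytic-signal (Hilbert) preprocessing first.
        Off by default: the encoded feature vectors are not bandpass
        signals and the time smoothing already suppresses the
        positive/negative interference.
    """
    x = validate_signal(x)
    if analytic:
        x = hilbert(np.real(x))
    N = x.shape[0]
    g = _as_window(g)
    H = _as_window(H)
    if g.odd_size > N:
        raise ValueError(f"time window size {g.odd_size} exceeds signal length {N}")
    if H.odd_size > 2 * N - 1:
        raise ValueError(f"lag window size {H.odd_size} exceeds lag support {2 * N - 1}")

    R = lag_product_array(x)
    gt = g.taps()
    Rs = fftconvolve(R, (gt / gt.sum())[:, None], mode="same")
    hw = np.zeros(2 * N - 1)
    half = (H.odd_size - 1) // 2
    center = N - 1
    hw[center - half : center + half + 1] = H.taps()
    return np.abs(_lag_dft(Rs * hw[None, :]))


def bin_to_frequency(k, N: int) -> np.ndarray:
    """Normalized frequency (cycles/sample) of output bin ``k``.

    Under the doubled-frequency convention bin ``k`` sits at ``k / (2N)``;
    for real input the spectrum is mirrored, so bins above ``N/2`` alias
    to ``(N - k) / (2N)``.
    """
    k = np.asarray(k)
    folded = np.minimum(k % N, (N - k) % N)
    return folded / (2 * N)
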