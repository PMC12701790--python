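"""Minimal wavelet transforms: multilevel Daubechies DWT and Morlet CWT.

Orthogonal Daubechies filter banks with circular (periodized) boundary
handling, which gives exact perfect reconstruction at every level for
even-length inputs, and a complex Morlet scalogram.  Filter coefficients
are the standard published values.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["DEC_LO", "dwt_max_level", "wavedec", "waverec", "morlet_scalogram"]

_SQRT2 = np.sqrt(2.0)
_SQRT3 = np.sqrt(3.0)

# Orthonormal scaling (low-pass) filters.  db2 from the closed form
# (1 +/- sqrt 3)/(4 sqrt 2); db4 are Daubechies' published 8-tap values.
DEC_LO: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array([1 + _SQRT3, 3 + _SQRT3, 3 - _SQRT3, 1 - _SQRT3]) / (4 * _SQRT2),
    "db4": np.array(
        [
            0.230377813308855,
            0.714846570552542,
            0.630880767929590,
            -0.027983769416984,
            -0.187034811718881,
            0.030841381835987,
            0.032883011666983,
            -0.010597401784997,
        ]
    ),
}


def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo = DEC_LO[wavelet]
    except KeyError:
        raise ValueError(f"unknown wavelet {wavelet!r}; choose from {sorted(DEC_LO)}") from None
    # quadrature mirror: hi[k] = (-1)^k lo[L-1-k]
    hi = lo[::-1] * (-1.0) ** np.arange(lo.size)
    return lo, hi


def _circ_convolve_down(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    n = x.size
    idx = (np.arange(n)[:, None] - np.arange(f.size)[None, :]) % n
    return (x[idx] @ f)[::2]


def dwt_max_level(n: int) -> int:
    """Number of halvings available before the length becomes odd or < 2."""
    level = 0
    while n >= 2 and n % 2 == 0:
        n //= 2
        level += 1
    return level


def wavedec(x, wavelet: str = "db4", level: int | None = None) -> list[np.ndarray]:
    """Multilevel DWT; returns ``[cA_L, cD_L, ..., cD_1]`` (pywt layout)."""
    x = np.asarray(x, dtype=float)
    lo, hi = _filters(wavelet)
    max_level = dwt_max_level(x.size)
    if level is None:
        level = max_level
    if level > max_level:
        raise ValueError(f"level {level} exceeds maximum {max_level} for length {x.size}")
    details = []
    approx = x
    for _ in range(level):
        details.append(_circ_convolve_down(approx, hi))
        approx = _circ_convolve_down(approx, lo)
    return [approx] + details[::-1]


def _circ_upsample_convolve(c: np.ndarray, f: np.ndarray) -> np.ndarray:
    n = 2 * c.size
    up = np.zeros(n)
    up[::2] = c
    idx = (np.arange(n)[:, None] + np.arange(f.size)[None, :]) % n
    return up[idx] @ f


def waverec(coeffs: list[np.ndarray], wavelet: str = "db4") -> np.ndarray:
    """Inverse of :func:`wavedec` (exact for periodized orthogonal filters)."""
    lo, hi = _filters(wavelet)
    approx = np.asarray(coeffs[0], dtype=float)
    for detail in coeffs[1:]:
        approx = _circ_upsample_convolve(approx, lo) + _circ_upsample_convolve(
            np.asarray(detail, dtype=float), hi
        )
    return approx


def morlet_wavelet(scale: float, w0: float = 6.0) -> np.ndarray:
    """Sampled complex Morlet wavelet at the given scale (L1-normalized)."""
    half = max(1, int(np.ceil(4.0 * scale)))
    t = np.arange(-half, half + 1)
    u = t / scale
    psi = np.pi ** (-0.25) * np.exp(1j * w0 * u) * np.exp(-0.5 * u**2)
    return psi / scale


def morlet_scales(n_scales: int, w0: float, length: int) -> np.ndarray:
    """Log-spaced scales spanning pseudo-frequencies ~0.5 down to ~2/length.

    The Morlet pseudo-frequency is ``w0 / (2 pi a)`` cycles/sample, so the
    scale range ``[w0/pi, w0 * length / (4 pi)]`` covers Nyquist down to
    two cycles per record.
    """
    lo = w0 / np.pi
    hi = w0 * length / (4 * np.pi)
    return np.geomspace(lo, hi, n_scales)


def morlet_scalogram(x, scales, w0: float = 6.0) -> np.ndarray:
    """|CWT| magnitude matrix, one row per scale, columns = time."""
    x = np.asarray(x, dtype=float)
    out = np.empty((len(scales), x.size))
    for i, a in enumerate(scales):
        psi = morlet_wavelet(a, w0)
        # correlation with the wavelet; 'same' keeps the signal's length
        out[i] = np.abs(fftconvolve(x, np.conj(psi)[::-1], mode="same"))
    return out
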