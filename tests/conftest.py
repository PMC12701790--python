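"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the FFT/convolution code paths of the
package: lag products via explicit double loops, the lag DFT via an
explicit complex-exponential sum, smoothing via explicit window sums, and
the Kaiser window via a truncated Bessel series.  They exist to pin the
implementation to the definitions.
"""

import numpy as np
import pytest

from vec2img.tfcore import kaiser_window


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- oracles


def lag_products_brute(x):
    """R(n, m) = x(n+m) x(n-m), zero outside the support; (N, 2N-1)."""
    x = np.asarray(x, dtype=float)
    N = x.size
    R = np.zeros((N, 2 * N - 1))
    for n in range(N):
        for m in range(-(N - 1), N):
            a, b = n + m, n - m
            if 0 <= a < N and 0 <= b < N:
                R[n, m + N - 1] = x[a] * x[b]
    return R


def lag_dft_brute(R):
    """Explicit sum over lags with kernel exp(-2j pi k m / N)."""
    N = R.shape[0]
    W = np.zeros((N, N), dtype=complex)
    for n in range(N):
        for k in range(N):
            acc = 0.0 + 0.0j
            for m in range(-(N - 1), N):
                acc += R[n, m + N - 1] * np.exp(-2j * np.pi * k * m / N)
            W[n, k] = acc
    return W


def wvd_brute(x):
    return lag_dft_brute(lag_products_brute(x)).real


def swvd_brute(x, Mg, Mh, beta=0.5):
    """Direct evaluation: time-smooth lag products with unit-sum Kaiser g,
    taper lags with Kaiser H centered at lag 0, then the explicit lag DFT,
    point-wise absolute value."""
    x = np.asarray(x, dtype=float)
    N = x.size
    Mg += 1 - Mg % 2  # center tap needs odd length
    Mh += 1 - Mh % 2
    g = kaiser_window(Mg, beta)
    g = g / g.sum()
    h = kaiser_window(Mh, beta)
    R = lag_products_brute(x)
    halfg = (Mg - 1) // 2
    Rs = np.zeros_like(R)
    for n in range(N):
        for p in range(-halfg, halfg + 1):
            if 0 <= n - p < N:
                Rs[n] += g[p + halfg] * R[n - p]
    halfh = (Mh - 1) // 2
    taper = np.zeros(2 * N - 1)
    for m in range(-halfh, halfh + 1):
        if abs(m) <= N - 1:
            taper[m + N - 1] = h[m + halfh]
    return np.abs(lag_dft_brute(Rs * taper[None, :]))


def auc_brute(y_true, scores):
    """Positive-negative pair counting, ties worth 1/2."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true]
    neg = scores[~y_true]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (pos.size * neg.size)


@pytest.fixture(scope="session")
def oracles():
    """Bundle of brute-force oracles for reuse in acceptance tests."""
    return {
        "lag_products": lag_products_brute,
        "wvd": wvd_brute,
        "swvd": swvd_brute,
        "auc": auc_brute,
    }
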