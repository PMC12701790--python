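"""Wigner-Ville core: lag products, windows, plain and smoothed WVD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vec2img.tfcore import (
    WindowSpec,
    kaiser_window,
    lag_product_array,
    swvd,
    wvd_plain,
)

from conftest import lag_products_brute, swvd_brute, wvd_brute


class TestLagProducts:
    def test_zero_signal_annihilates(self):
        assert np.all(lag_product_array(np.zeros(8)) == 0)

    def test_unit_impulse_single_entry(self):
        x = np.zeros(8)
        x[3] = 1.0
        R = lag_product_array(x)
        expected = np.zeros_like(R)
        expected[3, 7] = 1.0  # row n=3, lag m=0 (column offset N-1)
        np.testing.assert_array_equal(R, expected)

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=16)
        np.testing.assert_allclose(lag_product_array(x), lag_products_brute(x))

    @pytest.mark.parametrize("bad", [np.array([1.0, np.nan, 2.0]),
                                     np.array([1.0, np.inf]),
                                     np.ones((3, 3))])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            lag_product_array(bad)


class TestKaiserWindow:
    def test_single_point(self):
        np.testing.assert_array_equal(kaiser_window(1, 7.3), [1.0])

    def test_beta_zero_is_rectangular(self):
        np.testing.assert_allclose(kaiser_window(5, 0.0), np.ones(5))

    def test_matches_bessel_series(self):
        # independent evaluation of w[k] = I0(b sqrt(1-u^2)) / I0(b)
        def i0(z, terms=40):
            import math

            return sum((z / 2) ** (2 * j) / math.factorial(j) ** 2 for j in range(terms))

        M, beta = 8, 0.5
        k = np.arange(M)
        u = 2 * k / (M - 1) - 1
        expected = np.array([i0(beta * np.sqrt(1 - ui**2)) / i0(beta) for ui in u])
        np.testing.assert_allclose(kaiser_window(M, beta), expected, rtol=1e-12)

    def test_symmetry_peak_and_range(self):
        w = kaiser_window(9, 2.0)
        np.testing.assert_allclose(w, w[::-1])
        assert w.max() == w[4] == 1.0
        assert np.all((w > 0) & (w <= 1))

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            kaiser_window(0)
        with pytest.raises(ValueError):
            WindowSpec(-3)


class TestPlainWVD:
    def test_zero_signal(self):
        assert np.all(wvd_plain(np.zeros(8)) == 0)

    def test_matches_triple_loop(self, rng):
        x = rng.normal(size=16)
        np.testing.assert_allclose(wvd_plain(x), wvd_brute(x), rtol=1e-8, atol=1e-10)

    def test_time_marginal_proportional_to_energy(self, rng):
        # summing bins k=0..N-1 keeps only lag 0, with constant N
        x = rng.normal(size=32)
        W = wvd_plain(x)
        np.testing.assert_allclose(W.sum(axis=1), 32 * x**2, rtol=1e-10)

    def test_sinusoid_localizes_on_analytic_signal(self):
        # real-signal plain WVD carries a +/- interference line near DC
        # (the cross-term problem); the analytic signal localizes cleanly
        # at the doubled-frequency bin 2*k0
        N, k0 = 64, 9
        x = np.cos(2 * np.pi * k0 * np.arange(N) / N + 0.3)
        W = np.abs(wvd_plain(x, analytic=True))
        for n in range(4, N - 4):
            assert abs(int(np.argmax(W[n])) - 2 * k0) <= 1


class TestSWVD:
    def test_zero_signal(self):
        assert np.all(swvd(np.zeros(8), 3, 5) == 0)

    def test_degenerate_windows_reduce_to_plain(self, rng):
        # size-1 time window + rectangular lag window over the full
        # support leave the lag products untouched
        x = rng.normal(size=16)
        np.testing.assert_allclose(
            swvd(x, (1, 0.0), (31, 0.0)), np.abs(wvd_plain(x)), rtol=1e-9, atol=1e-12
        )

    def test_matches_direct_oracle(self, rng):
        x = rng.normal(size=32)
        got = swvd(x, (11, 0.5), (15, 0.5))
        np.testing.assert_allclose(got, swvd_brute(x, 11, 15), rtol=1e-8, atol=1e-10)

    def test_nonnegative_and_finite(self, rng):
        S = swvd(rng.normal(size=24), 7, 9)
        assert np.all(np.isfinite(S)) and np.all(S >= 0)

    def test_sinusoid_localizes_without_analytic_step(self):
        # time smoothing averages out the oscillating +/- interference,
        # so the raw real signal already localizes at bin 2*k0
        N, k0 = 64, 7
        x = np.cos(2 * np.pi * k0 * np.arange(N) / N + 1.1)
        S = swvd(x, 21, 21)
        # real input: spectrum mirrored, so 2*k0 and N-2*k0 are both true
        targets = (2 * k0, N - 2 * k0)
        for n in range(4, N - 4):
            am = int(np.argmax(S[n]))
            dist = min(min(abs(am - t), N - abs(am - t)) for t in targets)
            assert dist <= 1

    def test_smoothing_suppresses_cross_terms(self):
        # two-tone signal: the midpoint-frequency interference band of
        # |plain WVD| collapses under Kaiser smoothing
        N, k1, k2 = 64, 4, 12
        t = np.arange(N)
        for seed in range(5):
            r = np.random.default_rng(seed)
            ph = r.uniform(0, 2 * np.pi, 2)
            x = np.cos(2 * np.pi * k1 * t / N + ph[0]) + np.cos(2 * np.pi * k2 * t / N + ph[1])
            band = slice(k1 + k2 - 2, k1 + k2 + 3)  # doubled-frequency midpoint
            plain_peak = np.abs(wvd_plain(x))[:, band].max()
            smooth_peak = swvd(x, 31, 31)[:, band].max()
            assert smooth_peak < plain_peak

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            swvd(np.ones(8), 11, 5)
        with pytest.raises(ValueError):
            swvd(np.ones(8), 3, 17)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            swvd(np.array([1.0, np.nan, 0.0, 2.0]), 1, 3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    n=st.integers(min_value=8, max_value=24),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_swvd_fft_path_equals_direct_sum(n, seed):
    """Property: FFT-based SWVD equals the O(N^3) direct evaluation."""
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    Mg = 1 + 2 * int(r.integers(0, (n - 1) // 2 + 1))  # odd, <= n
    Mh = 1 + 2 * int(r.integers(0, n))  # odd, <= 2n - 1
    got = swvd(x, (Mg, 0.5), (Mh, 0.5))
    want = swvd_brute(x, Mg, Mh, 0.5)
    np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-9)
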