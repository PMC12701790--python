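"""Vector-to-image encoders: window sampling, composition, baselines, plumbing."""

import numpy as np
import pytest

from vec2img import _wavelets
from vec2img.encoders import (
    CWTEncoder,
    DWTEncoder,
    FeaturePermuter,
    MinMax255Scaler,
    ReshapeEncoder,
    WignerEncoder,
    encode_cwt,
    encode_dwt,
    encode_reshape,
    encode_wigner,
    normalize_0_255,
    permute_features,
    quadrant_compose,
    resize_to_backbone,
    sample_window_sizes,
)
from vec2img.tfcore import swvd


class TestWindowSampling:
    def test_ranges_and_ordering(self):
        rng = np.random.default_rng(0)
        N = 100
        for _ in range(1000):
            m1, m2, m3 = sample_window_sizes(N, rng)
            assert m1 <= m2 <= m3
            assert 29 <= m1 <= 51 and 49 <= m2 <= 71 and 69 <= m3 <= 91
            assert m1 % 2 == m2 % 2 == m3 % 2 == 1

    def test_seeded_determinism(self):
        a = sample_window_sizes(80, np.random.default_rng(42))
        b = sample_window_sizes(80, np.random.default_rng(42))
        assert a == b

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            sample_window_sizes(9, np.random.default_rng(0))


class TestWignerEncoding:
    def test_zero_vector_zero_tensor(self):
        t = encode_wigner(np.zeros(16), np.random.default_rng(0))
        assert t.shape == (16, 16, 3) and np.all(t == 0)

    def test_channels_equal_standalone_swvd(self, rng):
        x = rng.normal(size=64)
        sizes = (21, 35, 49)
        t = encode_wigner(x, window_sizes=sizes)
        for i, M in enumerate(sizes):
            np.testing.assert_array_equal(t[:, :, i], swvd(x, (M, 0.5), (M, 0.5)))

    def test_window_triples_differ_across_seeds(self, rng):
        x = rng.normal(size=64)
        triples = set()
        for seed in range(20):
            enc = WignerEncoder(random_state=seed).fit(x[None, :])
            triples.add(enc.window_sizes_)
        assert len(triples) > 1  # ensemble diversity

    def test_estimator_purity(self, rng):
        X = rng.normal(size=(3, 32))
        a = WignerEncoder(random_state=5).fit(X).transform(X)
        b = WignerEncoder(random_state=5).fit(X).transform(X)
        np.testing.assert_array_equal(a, b)


class TestQuadrantComposition:
    def test_shape_arithmetic(self, rng):
        t = quadrant_compose(rng.normal(size=256), np.random.default_rng(0))
        assert t.shape == (128, 128, 3)

    def test_equals_block_assembly(self, rng):
        x = rng.normal(size=256)
        triples = [(21, 31, 45), (23, 35, 51), (19, 33, 47), (25, 37, 49)]
        t = quadrant_compose(x, window_sizes=triples)
        segs = x.reshape(4, 64)
        blocks = [encode_wigner(s, window_sizes=tr) for s, tr in zip(segs, triples)]
        np.testing.assert_array_equal(t[:64, :64], blocks[0])
        np.testing.assert_array_equal(t[:64, 64:], blocks[1])
        np.testing.assert_array_equal(t[64:, :64], blocks[2])
        np.testing.assert_array_equal(t[64:, 64:], blocks[3])

    def test_identical_segments_identical_quadrants(self, rng):
        seg = rng.normal(size=64)
        x = np.tile(seg, 4)
        t = quadrant_compose(x, np.random.default_rng(3), share_windows=True)
        np.testing.assert_array_equal(t[:64, :64], t[64:, 64:])
        np.testing.assert_array_equal(t[:64, 64:], t[64:, :64])

    def test_zero_vector(self):
        assert np.all(quadrant_compose(np.zeros(256), np.random.default_rng(0)) == 0)

    def test_padding_to_multiple_of_four(self, rng):
        t = quadrant_compose(rng.normal(size=250), np.random.default_rng(0))
        assert t.shape == (126, 126, 3)  # padded to 252, segments of 63

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError, match="encode directly"):
            quadrant_compose(np.ones(30), np.random.default_rng(0))


class TestReshapeEncoder:
    def test_row_major_grid(self):
        t = encode_reshape(np.arange(1, 10, dtype=float))
        np.testing.assert_array_equal(t[:, :, 0], [[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        np.testing.assert_array_equal(t[:, :, 0], t[:, :, 1])
        np.testing.assert_array_equal(t[:, :, 0], t[:, :, 2])

    def test_padding(self):
        t = encode_reshape(np.arange(1, 9, dtype=float))
        assert t.shape == (3, 3, 3) and t[2, 2, 0] == 0

    def test_round_trip(self, rng):
        x = rng.normal(size=13)
        t = encode_reshape(x)
        np.testing.assert_array_equal(t[:, :, 0].ravel()[:13], x)


class TestCWTEncoder:
    def test_zero_vector(self):
        assert np.all(encode_cwt(np.zeros(32)) == 0)

    def test_shape_and_nonnegativity(self, rng):
        t = encode_cwt(rng.normal(size=48))
        assert t.shape == (48, 48, 3) and np.all(t >= 0)

    def test_sinusoid_peaks_at_matching_scale(self):
        # strongest scalogram row at the scale whose Morlet
        # pseudo-frequency w0/(2 pi a) matches the sinusoid, within one step
        L, k0 = 64, 8
        x = np.sin(2 * np.pi * k0 * np.arange(L) / L)
        t = encode_cwt(x)
        from vec2img.encoders import CWT_W0

        for i, w0 in enumerate(CWT_W0):
            scales = _wavelets.morlet_scales(L, w0, L)
            # central columns avoid the cone of influence at the edges
            energy = t[:, L // 4 : 3 * L // 4, i].sum(axis=1)
            expected = np.argmin(np.abs(scales - w0 / (2 * np.pi * k0 / L)))
            assert abs(int(np.argmax(energy)) - expected) <= 1


class TestDWTEncoder:
    def test_zero_vector(self):
        assert np.all(encode_dwt(np.zeros(64)) == 0)

    def test_constant_vector_vanishing_details(self):
        coeffs = _wavelets.wavedec(np.full(64, 3.7), "db4")
        for detail in coeffs[1:]:
            assert np.max(np.abs(detail)) < 1e-10
        assert np.max(np.abs(coeffs[0])) > 0

    @pytest.mark.parametrize("wavelet", ["haar", "db2", "db4"])
    def test_perfect_reconstruction(self, rng, wavelet):
        x = rng.normal(size=128)
        coeffs = _wavelets.wavedec(x, wavelet)
        np.testing.assert_allclose(_wavelets.waverec(coeffs, wavelet), x, atol=1e-8)

    def test_shape(self, rng):
        t = encode_dwt(rng.normal(size=100))  # padded to 128 -> 12x12 grid
        assert t.shape == (12, 12, 3)


class TestNormalization:
    def test_affine_map_definition(self):
        train = np.array([[0.0], [1.0], [2.0]])
        np.testing.assert_allclose(normalize_0_255(train).ravel(), [0, 127.5, 255])

    def test_extrapolation_not_clipped(self):
        train = np.array([[0.0], [2.0]])
        out = normalize_0_255(train, np.array([[3.0]]))
        np.testing.assert_allclose(out, [[382.5]])

    def test_constant_column_maps_to_zero(self):
        train = np.full((4, 2), 5.0)
        assert np.all(normalize_0_255(train) == 0)

    def test_no_leakage_from_test_rows(self, rng):
        train = rng.normal(size=(20, 6))
        test = rng.normal(size=(10, 6))
        s1 = MinMax255Scaler().fit(train)
        s2 = MinMax255Scaler().fit(train)
        _ = s2.transform(test[::-1])  # permuted test rows
        np.testing.assert_array_equal(s1.data_min_, s2.data_min_)
        np.testing.assert_array_equal(s1.data_max_, s2.data_max_)
        np.testing.assert_array_equal(s1.transform(test), s2.transform(test))


class TestFeaturePermutation:
    def test_seeded_and_shared(self, rng):
        train = rng.normal(size=(8, 10))
        test = rng.normal(size=(4, 10))
        tr1, te1, p1 = permute_features(train, test, seed=3)
        tr2, te2, p2 = permute_features(train, test, seed=3)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(tr1, tr2)
        # identical permutation on both partitions
        np.testing.assert_array_equal(te1, test[:, p1])
        np.testing.assert_array_equal(tr1, train[:, p1])

    def test_inverse_recovers_order(self, rng):
        X = rng.normal(size=(5, 12))
        perm = FeaturePermuter(random_state=0).fit(X)
        np.testing.assert_array_equal(perm.inverse_transform(perm.transform(X)), X)


class TestResize:
    def test_identity_at_target(self, rng):
        t = rng.normal(size=(16, 16, 3))
        np.testing.assert_array_equal(resize_to_backbone(t, 16), t)

    def test_constant_preserved(self):
        t = np.full((8, 8, 3), 2.5)
        out = resize_to_backbone(t, 20)
        np.testing.assert_allclose(out, 2.5)

    def test_bilinear_stays_in_range(self, rng):
        t = rng.normal(size=(64, 64, 3))
        out = resize_to_backbone(t, 224)
        assert out.min() >= t.min() - 1e-9 and out.max() <= t.max() + 1e-9

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            resize_to_backbone(np.ones((8, 8, 3)), 1)


@pytest.mark.parametrize(
    "encoder",
    [WignerEncoder(random_state=0), ReshapeEncoder(), CWTEncoder(), DWTEncoder()],
    ids=["wigner", "reshape", "cwt", "dwt"],
)
def test_encoders_are_pure_and_three_channel(encoder, rng):
    X = rng.normal(size=(2, 64))
    from sklearn.base import clone

    a = clone(encoder).fit(X).transform(X)
    b = clone(encoder).fit(X).transform(X)
    np.testing.assert_array_equal(a, b)
    assert a.shape[0] == 2 and a.shape[3] == 3
    assert np.all(np.isfinite(a))
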