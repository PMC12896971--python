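"""Handcrafted descriptors: LBP vs brute force, Gabor tuning, HSI color
conversion, similarity transforms, moment and Fourier-descriptor
invariances."""

import numpy as np
import pytest

from quadrasense.feat_hand import (
    _LBP_OFFSETS,
    FourierDescriptorSet,
    GaborBankConfig,
    apply_similarity_transform,
    fourier_descriptors,
    gabor_features,
    handcrafted_vector,
    hsi_statistics,
    lbp_code,
    lbp_histogram,
    mask_contour,
    moment_invariants,
    rgb_to_hsi,
    shape_distance,
)


def _lbp_histogram_oracle(img):
    """Independent double loop over interior pixels."""
    hist = np.zeros(256)
    for i in range(1, img.shape[0] - 1):
        for j in range(1, img.shape[1] - 1):
            code = 0
            for n, (dr, dc) in enumerate(_LBP_OFFSETS):
                if img[i + dr, j + dc] - img[i, j] >= 0:
                    code |= 1 << n
            hist[code] += 1
    return hist / hist.sum()


class TestLBP:
    def test_constant_window_all_bits_set(self):
        assert lbp_code(np.full((3, 3), 7.0)) == 255

    def test_dominant_center_zero(self):
        w = np.zeros((3, 3))
        w[1, 1] = 10
        assert lbp_code(w) == 0

    def test_single_bit(self):
        w = np.zeros((3, 3))
        w[1, 1] = 5
        w[0, 0] = 5  # neighbor n=0 (top-left) >= center
        assert lbp_code(w) == 1

    def test_wrong_window_rejected(self):
        with pytest.raises(ValueError):
            lbp_code(np.zeros((4, 4)))

    def test_constant_image_unit_mass_at_255(self):
        h = lbp_histogram(np.full((6, 6), 3.0))
        assert h[255] == 1.0 and h.sum() == 1.0

    def test_histogram_matches_oracle_on_random_images(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            img = rng.integers(0, 256, size=(8, 8)).astype(float)
            np.testing.assert_array_equal(lbp_histogram(img),
                                          _lbp_histogram_oracle(img))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            lbp_histogram(np.zeros((2, 5)))


class TestGabor:
    def test_constant_image_zero_sd(self):
        feats = gabor_features(np.full((32, 32), 0.7))
        sds = feats[1::2]
        assert np.all(sds < 1e-6)

    def test_output_length(self):
        bank = GaborBankConfig(center_freqs=(0.1, 0.2), orientations=(0.0, np.pi / 2))
        assert gabor_features(np.zeros((16, 16)), bank).shape == (8,)

    def test_grating_orientation_tuning(self):
        """A horizontal-frequency grating excites the 0-degree filter more
        than the orthogonal one at the same frequency."""
        x = np.arange(48)
        grating = np.tile(np.sin(2 * np.pi * 0.2 * x), (48, 1))
        bank = GaborBankConfig(center_freqs=(0.2,), orientations=(0.0, np.pi / 2))
        feats = gabor_features(grating, bank)
        mean_tuned, mean_ortho = feats[0], feats[2]
        assert mean_tuned > mean_ortho


class TestHSI:
    def test_achromatic_gray(self):
        h, s, i = rgb_to_hsi(np.array([0.5, 0.5, 0.5]))
        assert (h, s, i) == (0.0, 0.0, 0.5)

    def test_pure_red(self):
        h, s, i = rgb_to_hsi(np.array([1.0, 0.0, 0.0]))
        assert h == pytest.approx(0.0)
        assert s == pytest.approx(1.0)
        assert i == pytest.approx(1 / 3)

    def test_pure_green_hue_120(self):
        h, _, _ = rgb_to_hsi(np.array([0.0, 1.0, 0.0]))
        assert h == pytest.approx(120.0, abs=1e-9)

    def test_black_pixel_convention(self):
        assert rgb_to_hsi(np.zeros(3)) == (0.0, 0.0, 0.0)

    def test_statistics_length_and_constant_image(self):
        img = np.tile(np.array([0.2, 0.5, 0.3]), (8, 8, 1))
        stats = hsi_statistics(img)
        assert stats.shape == (8,)
        assert np.allclose(stats[1::2], 0.0, atol=1e-12)  # all sds zero

    def test_red_green_halves_fully_saturated(self):
        img = np.zeros((4, 8, 3))
        img[:, :4, 0] = 1.0
        img[:, 4:, 1] = 1.0
        stats = hsi_statistics(img)
        mean_s = stats[4]
        assert mean_s == pytest.approx(1.0)


class TestSimilarityTransform:
    def test_identity(self, rng):
        pts = rng.random((10, 2))
        np.testing.assert_allclose(apply_similarity_transform(pts), pts)

    def test_quarter_turn(self):
        out = apply_similarity_transform(np.array([[1.0, 0.0]]), theta=np.pi / 2)
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_anisotropic_scale(self):
        out = apply_similarity_transform(np.array([[3.0, 4.0]]), Sx=2.0)
        np.testing.assert_allclose(out, [[6.0, 4.0]])

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            apply_similarity_transform(np.zeros((1, 2)), Sx=0.0)


def _disk_mask(side, cx, cy, r):
    yy, xx = np.mgrid[0:side, 0:side]
    return ((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r).astype(np.uint8)


class TestMoments:
    def test_single_pixel(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[4, 6] = 1  # x=6 (column), y=4 (row)
        ms = moment_invariants(mask)
        assert ms.raw[(0, 0)] == 1
        assert ms.centroid == (6.0, 4.0)
        assert all(v == 0 for (p, q), v in ms.central.items() if p + q >= 1)

    def test_translation_invariance_exact(self):
        base = _disk_mask(40, 12, 14, 6)
        shifted = np.roll(np.roll(base, 7, axis=0), 5, axis=1)
        a = moment_invariants(base)
        b = moment_invariants(shifted)
        for pq in a.central:
            assert a.central[pq] == pytest.approx(b.central[pq], abs=1e-9)
            assert a.normalized[pq] == pytest.approx(b.normalized[pq], abs=1e-12)

    def test_scale_invariance_on_disk(self):
        small = _disk_mask(50, 25, 25, 10)
        big = np.kron(small, np.ones((2, 2), dtype=np.uint8))  # 2x upsample
        a = moment_invariants(small)
        b = moment_invariants(big)
        for pq, va in a.normalized.items():
            if pq == (0, 0):
                continue
            vb = b.normalized[pq]
            assert abs(vb - va) <= 0.03 * max(abs(va), 1e-3)

    def test_eta00_is_one(self):
        ms = moment_invariants(_disk_mask(30, 15, 15, 8))
        assert ms.normalized[(0, 0)] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            moment_invariants(np.zeros((5, 5)))


def _circle(n=64, r=1.0, center=(0, 0), phase=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], axis=1)


class TestFourierDescriptors:
    def test_circle_single_harmonic(self):
        fd = fourier_descriptors(_circle(r=2.5), N=64)
        assert abs(abs(fd.coeffs[1]) - 2.5) < 1e-9
        others = np.abs(np.concatenate([fd.coeffs[2:], fd.coeffs[:1]]))
        assert others.max() < 1e-9

    def test_normalized_length(self):
        fd = fourier_descriptors(_circle(), N=64)
        assert len(fd.normalized) == 62

    def test_rotation_scale_start_invariance(self):
        base = _circle(n=64, r=1.0) + np.array([0.3, -0.2])
        sq = base * np.array([1.0, 0.6])  # ellipse, richer spectrum
        fd0 = fourier_descriptors(sq, N=64)
        rot = apply_similarity_transform(sq, theta=1.1)
        fd1 = fourier_descriptors(rot, N=64)
        scaled = sq * 3.0
        fd2 = fourier_descriptors(scaled, N=64)
        rolled = np.roll(sq, 37, axis=0)
        fd3 = fourier_descriptors(rolled, N=64)
        for other in (fd1, fd2, fd3):
            np.testing.assert_allclose(other.normalized, fd0.normalized,
                                       atol=1e-9)

    def test_degenerate_contour_rejected(self):
        pts = np.tile([[1.0, 1.0]], (10, 1))
        with pytest.raises(ValueError):
            fourier_descriptors(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fourier_descriptors(_circle(n=5))


class TestShapeDistance:
    def test_identity_zero_and_symmetry(self, rng):
        a = fourier_descriptors(_circle(r=1) * np.array([1, 0.7]), N=32)
        b = fourier_descriptors(_circle(r=1) * np.array([1, 0.4]), N=32)
        assert shape_distance(a, a) == 0.0
        assert shape_distance(a, b) == pytest.approx(shape_distance(b, a))

    def test_scaled_circle_distance_zero(self):
        a = fourier_descriptors(_circle(r=1.0), N=64)
        b = fourier_descriptors(_circle(r=2.0), N=64)
        assert shape_distance(a, b) < 1e-9

    def test_length_mismatch_rejected(self):
        a = fourier_descriptors(_circle(), N=32)
        b = fourier_descriptors(_circle(), N=64)
        with pytest.raises(ValueError):
            shape_distance(a, b)


class TestHandcraftedVector:
    def test_block_index_contiguous(self, small_dataset):
        p = small_dataset[0]
        vec, idx = handcrafted_vector(p.image, p.mask_true)
        spans = sorted(idx.values())
        assert spans[0][0] == 0
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c
        assert spans[-1][1] == len(vec)

    def test_deterministic(self, small_dataset):
        p = small_dataset[0]
        v1, _ = handcrafted_vector(p.image, p.mask_true)
        v2, _ = handcrafted_vector(p.image, p.mask_true)
        np.testing.assert_array_equal(v1, v2)

    def test_finite_on_constant_patch(self):
        vec, _ = handcrafted_vector(np.full((32, 32, 3), 0.5), None)
        assert np.all(np.isfinite(vec))

    def test_mask_translation_leaves_shape_blocks(self):
        mask = _disk_mask(64, 20, 20, 8)
        shifted = np.roll(np.roll(mask, 9, axis=0), -4, axis=1)
        img = np.random.default_rng(0).random((64, 64, 3))
        v1, idx = handcrafted_vector(img, mask)
        v2, _ = handcrafted_vector(img, shifted)
        for block in ("moments", "fd"):
            a, b = idx[block]
            np.testing.assert_allclose(v1[a:b], v2[a:b], atol=1e-6)

    def test_contour_extraction_on_disk(self):
        contour = mask_contour(_disk_mask(40, 20, 20, 9))
        assert contour is not None and len(contour) >= 8
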