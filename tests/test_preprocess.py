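"""Preprocessing: z-score, OD transform, Macenko estimation, median
filter vs a sorting oracle, histogram equalization vs the closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadrasense.preprocess import (
    DegenerateInputError,
    InsufficientTissueError,
    estimate_stain_vectors,
    histogram_equalize,
    macenko_normalize,
    median_filter,
    od_to_rgb,
    preprocess_patch,
    rgb_to_od,
    stain_concentrations,
    zero_mean_normalize,
)
from quadrasense.synth import RUIFROK_HE, SynthConfig, generate_patch


class TestZeroMean:
    def test_hand_example(self):
        img = np.array([[1.0], [2.0], [3.0]])  # one channel, three pixels
        out, params = zero_mean_normalize(img[..., None])
        np.testing.assert_allclose(out.ravel(), [-1, 0, 1], atol=1e-12)
        assert params.mu[0] == 2 and params.sigma[0] == 1  # n-1 denominator

    def test_output_standardized(self, rng):
        img = rng.random((16, 16, 3))
        out, _ = zero_mean_normalize(img)
        for c in range(3):
            assert abs(out[..., c].mean()) < 1e-9
            assert abs(out[..., c].std(ddof=1) - 1) < 1e-9

    def test_constant_channel_rejected(self):
        img = np.full((4, 4, 3), 0.5)
        img[..., 0] = np.random.default_rng(0).random((4, 4))
        with pytest.raises(DegenerateInputError):
            zero_mean_normalize(img)


class TestOpticalDensity:
    @pytest.mark.parametrize("intensity,od", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decades(self, intensity, od):
        assert rgb_to_od(np.array([intensity]), epsilon=1e-6)[0] == pytest.approx(od)

    def test_round_trip_above_epsilon(self, rng):
        img = rng.uniform(0.05, 1.0, size=(8, 8, 3))
        np.testing.assert_allclose(od_to_rgb(rgb_to_od(img)), img, atol=1e-12)


class TestStainEstimation:
    def test_recovers_known_vectors(self, clean_mitotic_patch):
        cfg, patch = clean_mitotic_patch
        od = rgb_to_od(patch.image).reshape(-1, 3)
        model = estimate_stain_vectors(od, alpha=1.0, beta=0.15)
        for i in range(2):
            cos = abs(model.V[:, i] @ cfg.stain_matrix_true[:, i])
            assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_hematoxylin_column_first(self, clean_mitotic_patch):
        _, patch = clean_mitotic_patch
        model = estimate_stain_vectors(rgb_to_od(patch.image).reshape(-1, 3))
        assert model.V[2, 0] > model.V[2, 1]  # more blue absorption first

    def test_pixel_order_and_duplication_invariance(self, clean_mitotic_patch):
        _, patch = clean_mitotic_patch
        od = rgb_to_od(patch.image).reshape(-1, 3)
        m1 = estimate_stain_vectors(od)
        m2 = estimate_stain_vectors(od[::-1])
        m3 = estimate_stain_vectors(np.vstack([od, od]))
        np.testing.assert_allclose(m1.V, m2.V, atol=1e-9)
        np.testing.assert_allclose(m1.V, m3.V, atol=1e-9)

    def test_insufficient_tissue(self):
        white = np.full((50, 3), 0.01)  # OD norm ~ 0.02 < beta
        with pytest.raises(InsufficientTissueError):
            estimate_stain_vectors(white * 0 + 0.001)

    def test_single_stain_degenerate(self):
        od = np.outer(np.linspace(0.5, 1.5, 100), RUIFROK_HE[:, 0])
        with pytest.raises(DegenerateInputError):
            estimate_stain_vectors(od)


class TestConcentrations:
    def test_exact_linear_system(self, rng):
        from quadrasense.preprocess import StainModel
        model = StainModel(V=RUIFROK_HE.copy(), maxC=np.ones(2))
        S0 = rng.uniform(0, 2, size=(30, 2))
        od = S0 @ model.V.T
        np.testing.assert_allclose(stain_concentrations(od, model), S0, atol=1e-9)

    def test_pure_first_stain(self):
        from quadrasense.preprocess import StainModel
        model = StainModel(V=RUIFROK_HE.copy(), maxC=np.ones(2))
        S = stain_concentrations(RUIFROK_HE[:, 0][None], model)
        np.testing.assert_allclose(S, [[1.0, 0.0]], atol=1e-9)

    def test_zero_od(self):
        from quadrasense.preprocess import StainModel
        model = StainModel(V=RUIFROK_HE.copy(), maxC=np.ones(2))
        np.testing.assert_allclose(
            stain_concentrations(np.zeros((1, 3)), model), [[0, 0]], atol=1e-12)


class TestMacenkoNormalize:
    def test_self_target_round_trip(self, clean_mitotic_patch):
        _, patch = clean_mitotic_patch
        model = estimate_stain_vectors(rgb_to_od(patch.image).reshape(-1, 3))
        out = macenko_normalize(patch.image, model)
        assert np.abs(out - patch.image).max() < 1e-3

    def test_cross_stain_concentration_agreement(self, clean_mitotic_patch):
        """Two patches with different true stain matrices, normalized to
        one target, must agree in per-stain 99th-percentile concentration."""
        _, patch_a = clean_mitotic_patch
        v2 = np.array([[0.55, 0.10], [0.75, 0.95], [0.37, 0.30]])
        v2 /= np.linalg.norm(v2, axis=0)
        cfg_b = SynthConfig(patch_size=64, noise_sd=0.0, stain_matrix_true=v2,
                            seed=9, nucleus_radius=4.0, mitosis_radius=5.0)
        patch_b = generate_patch(cfg_b, label=1, seed=9)
        target = estimate_stain_vectors(rgb_to_od(patch_a.image).reshape(-1, 3))
        p99 = []
        for img in (patch_a.image, patch_b.image):
            normed = macenko_normalize(img, target)
            conc = stain_concentrations(rgb_to_od(normed), target)
            p99.append(np.percentile(conc.reshape(-1, 2), 99, axis=0))
        np.testing.assert_allclose(p99[0], p99[1], rtol=0.02)

    def test_pure_white_rejected(self):
        with pytest.raises(InsufficientTissueError):
            macenko_normalize(np.ones((16, 16, 3)), None)


def _median_oracle(img, w):
    """Brute-force sorting median with replicate padding."""
    h = w // 2
    padded = np.pad(img, h, mode="edge")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sort(padded[i : i + w, j : j + w].ravel())[w * w // 2]
    return out


class TestMedianFilter:
    def test_center_outlier(self):
        img = np.array([[1, 2, 3], [4, 100, 6], [7, 8, 9]], dtype=float)
        assert median_filter(img, 3)[1, 1] == 6

    def test_constant_unchanged(self):
        img = np.full((6, 6), 3.0)
        np.testing.assert_array_equal(median_filter(img, 3), img)

    def test_salt_impulse_removed(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        assert median_filter(img, 3).max() == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4)), 4)

    def test_matches_sorting_oracle_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            img = rng.integers(0, 256, size=(9, 9)).astype(float)
            w = int(rng.choice([3, 5]))
            np.testing.assert_array_equal(median_filter(img, w),
                                          _median_oracle(img, w))


def _histeq_oracle(ch, levels):
    counts = np.bincount(ch.ravel(), minlength=levels)
    cdf = np.cumsum(counts) / counts.sum()
    out = np.empty_like(ch)
    for i in range(ch.shape[0]):
        for j in range(ch.shape[1]):
            out[i, j] = round((levels - 1) * cdf[ch[i, j]])
    return out


class TestHistogramEqualize:
    def test_constant_image_maps_to_top_level(self):
        img = np.full((5, 5), 17, dtype=np.int64)
        out, m = histogram_equalize(img, levels=256)
        assert np.all(out == 255)
        assert m.cdf[17] == 1.0

    def test_two_level_half_and_half(self):
        img = np.zeros((2, 256), dtype=np.int64)
        img[:, 128:] = 255
        out, _ = histogram_equalize(img, levels=256)
        assert set(np.unique(out)) == {128, 255}

    def test_uniform_histogram_near_identity(self):
        img = np.tile(np.arange(256, dtype=np.int64), (2, 1))
        out, m = histogram_equalize(img, levels=256)
        assert np.abs(out.astype(int) - img).max() <= 1
        assert np.all(np.diff(m.lut.astype(int)) >= 0)

    def test_matches_per_pixel_oracle(self, rng):
        img = rng.integers(0, 64, size=(12, 12))
        out, _ = histogram_equalize(img, levels=64)
        np.testing.assert_array_equal(out, _histeq_oracle(img, 64))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_within_one_level(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, size=(16, 16))
        once, _ = histogram_equalize(img, 256)
        twice, _ = histogram_equalize(once, 256)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_equalize(np.zeros((0,), dtype=np.int64))


class TestFullPipeline:
    def test_runs_and_stays_in_range(self, small_dataset):
        out, info = preprocess_patch(small_dataset[0].image)
        assert out.shape == small_dataset[0].image.shape
        assert out.min() >= 0 and out.max() <= 1
        assert {"zscore", "stain", "histeq"} <= set(info)
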