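import itertools

import numpy as np
import pytest

from thyrotex.texture_features import (
    DegenerateInputError,
    FEATURE_NAMES,
    QuadtreeResult,
    extract_feature_vector,
    feature_table,
    filtered_histogram_minimum,
    glcm_build,
    glcm_features,
    power_spectrum_mean,
    quadtree_decompose,
    quadtree_features,
    regional_minima_map,
    regional_minima_mean,
    smoothness,
)
from oracles import plateau_minima, quadtree_area, sum_of_squares


class TestPowerSpectrumMean:
    def test_single_pixel_is_squared_value(self):
        assert power_spectrum_mean(np.array([[7]], dtype=np.uint8)) == pytest.approx(49.0)

    def test_constant_image_only_dc_term(self):
        img = np.full((5, 8), 13, dtype=np.uint8)
        assert power_spectrum_mean(img) == pytest.approx(5 * 8 * 13**2)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("shape", [(8, 8), (6, 11), (1, 5)])
    def test_parseval_identity(self, seed, shape):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=shape).astype(np.uint8)
        assert power_spectrum_mean(img) == pytest.approx(sum_of_squares(img), rel=1e-10)


class TestRegionalMinima:
    def _three_foci(self):
        img = np.full((7, 7), 40, dtype=np.uint8)
        img[1, 1], img[3, 4], img[5, 2] = 1, 2, 9
        return img

    def test_isolated_dark_foci_are_separated(self):
        img = self._three_foci()
        mask = regional_minima_map(img)
        assert mask.sum() == 3
        assert sorted(img[mask].tolist()) == [1, 2, 9]

    def test_mean_of_single_pixel_foci(self):
        assert regional_minima_mean(self._three_foci()) == pytest.approx((1 + 2 + 9) / 3)

    def test_literal_min_option(self):
        assert regional_minima_mean(self._three_foci(), reduce="min") == 1.0

    def test_constant_image_is_one_plateau(self):
        img = np.full((4, 6), 40, dtype=np.uint8)
        assert regional_minima_map(img).all()
        assert regional_minima_mean(img) == 40.0

    def test_exhaustive_three_level_3x3_against_plateau_oracle(self):
        for bits in itertools.product(range(3), repeat=9):
            img = (np.array(bits, dtype=np.uint8) * 100).reshape(3, 3)
            np.testing.assert_array_equal(
                regional_minima_map(img), plateau_minima(img), err_msg=str(img)
            )

    @pytest.mark.parametrize("seed", range(50))
    def test_random_three_level_4x4_against_plateau_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = (rng.integers(0, 3, size=(4, 4)) * 100).astype(np.uint8)
        np.testing.assert_array_equal(regional_minima_map(img), plateau_minima(img))

    def test_bounded_by_image_range(self, random_image):
        w2 = regional_minima_mean(random_image)
        assert random_image.min() <= w2 <= random_image.max()


class TestSmoothness:
    def test_constant_image_is_zero(self):
        assert smoothness(np.full((4, 4), 200, dtype=np.uint8)) == 0.0

    def test_half_black_half_white(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[:, 2:] = 255
        # sigma = 0.5 on the unit scale
        assert smoothness(img) == pytest.approx(1 - 1 / 1.25)

    def test_monotone_in_dispersion_and_below_one(self):
        values = []
        for d in (10, 40, 100):
            img = np.full((4, 4), 128, dtype=np.uint8)
            img[::2] = 128 - d
            img[1::2] = 128 + d
            values.append(smoothness(img))
        assert values == sorted(values)
        assert all(0 <= v < 1 for v in values)


class TestFilteredHistogramMinimum:
    def test_constant_image(self):
        assert filtered_histogram_minimum(np.full((3, 3), 77, dtype=np.uint8)) == 77.0

    def _mixed_image(self):
        # 100 px of 50, 10 px of 7, 30 px of 12 on a 10x14 grid
        vals = np.array([50] * 100 + [7] * 10 + [12] * 30, dtype=np.uint8)
        return vals.reshape(10, 14)

    def test_sparse_dark_bin_suppressed(self):
        # bin 7 holds 10 <= 20% of modal 100 and is skipped; bin 12 survives
        assert filtered_histogram_minimum(self._mixed_image()) == 12.0

    def test_isolated_zero_pixels_ignored_but_move_minima_mean(self):
        img = self._mixed_image()
        img2 = img.copy()
        img2[0, [0, 3, 6, 9, 12]] = 0  # five isolated black pixels
        assert filtered_histogram_minimum(img2) == filtered_histogram_minimum(img)
        assert regional_minima_mean(img2) != regional_minima_mean(img)

    def test_bounded_by_image_range(self, random_image):
        w4 = filtered_histogram_minimum(random_image)
        assert random_image.min() <= w4 <= random_image.max()


class TestGlcm:
    @pytest.mark.parametrize("seed", range(5))
    def test_4x5_image_yields_16_horizontal_pairs(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(4, 5)).astype(np.uint8)
        g = glcm_build(img)
        assert g.raw.sum() == 16

    def test_pair_counts_and_invariants(self, random_image):
        m, n = random_image.shape
        g = glcm_build(random_image)
        assert g.raw.sum() == m * (n - 1)
        assert g.symmetric.sum() == 2 * m * (n - 1)
        np.testing.assert_array_equal(g.symmetric, g.symmetric.T)
        assert g.normalized.sum() == pytest.approx(1.0, abs=1e-12)
        assert set(np.unique(g.binary)) <= {0, 1}

    def test_single_repeated_pair(self):
        img = np.array([[9, 9]], dtype=np.uint8)
        g = glcm_build(img)
        assert g.raw[9, 9] == 1
        assert g.symmetric[9, 9] == 2
        assert g.raw.sum() == 1

    def test_single_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            glcm_build(np.array([[1], [2]], dtype=np.uint8))


class TestGlcmFeatures:
    def test_constant_image_single_cell(self):
        g = glcm_build(np.full((4, 4), 30, dtype=np.uint8))
        w5, w6 = glcm_features(g)
        assert w6 == 1.0
        assert w5 == pytest.approx(np.sqrt(2) * 31)

    def test_brightening_increases_w5_not_w6(self, rng):
        img = rng.integers(40, 120, size=(8, 8)).astype(np.uint8)
        w5a, w6a = glcm_features(glcm_build(img))
        w5b, w6b = glcm_features(glcm_build(img + 50))  # no clipping: max < 170+50
        assert w5b > w5a
        assert w6b == w6a

    def test_alternating_pair_centroid(self):
        a, b = 10, 20
        img = np.array([[a, b, a, b]], dtype=np.uint8)
        g = glcm_build(img)
        assert g.binary.sum() == 2
        w5, w6 = glcm_features(g)
        centre = (a + b) / 2 + 1
        assert w5 == pytest.approx(np.sqrt(2) * centre)
        assert w6 == 2.0

    def test_empty_binary_rejected(self):
        g = glcm_build(np.full((2, 2), 5, dtype=np.uint8))
        g.binary = np.zeros_like(g.binary)
        with pytest.raises(DegenerateInputError):
            glcm_features(g)


class TestQuadtree:
    def test_constant_image_single_block(self):
        q = quadtree_decompose(np.full((8, 8), 99, dtype=np.uint8))
        assert q.counts == {8: 1}
        assert q.side == 8

    def test_checkerboard_fully_split(self):
        img = (np.indices((8, 8)).sum(0) % 2 * 255).astype(np.uint8)
        q = quadtree_decompose(img)
        assert q.counts == {1: 64}

    def test_range_at_threshold_not_split(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        img[0, 0] = 125  # range 25 <= 0.1*255
        assert quadtree_decompose(img).counts == {8: 1}

    def test_non_power_of_two_centrally_cropped(self, rng):
        img = rng.integers(0, 256, size=(20, 37)).astype(np.uint8)
        q = quadtree_decompose(img)
        assert q.side == 16
        assert quadtree_area(q.counts) == 16 * 16

    @pytest.mark.parametrize("seed", range(10))
    def test_tiling_conservation(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        q = quadtree_decompose(img)
        assert quadtree_area(q.counts) == 32 * 32

    def test_threshold_extremes(self, rng):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)  # all values distinct
        assert quadtree_decompose(img, t=0.0).counts == {1: 256}
        assert quadtree_decompose(img, t=1.0).counts == {16: 1}


class TestQuadtreeFeatures:
    def test_published_style_normalisation(self):
        q = QuadtreeResult({1: 0, 2: 32, 4: 152, 8: 148}, side=128, threshold=0.1)
        w7, w8, w9, w10 = quadtree_features(q, 128, 128)
        assert w7 == 0.0
        assert w8 == pytest.approx(32 * 2 / 16384)
        assert w9 == pytest.approx(152 * 4 / 16384)
        assert w10 == pytest.approx(148 * 8 / 16384)

    def test_constant_image_only_w10(self):
        q = quadtree_decompose(np.full((8, 8), 5, dtype=np.uint8))
        assert quadtree_features(q) == (0.0, 0.0, 0.0, pytest.approx(1 * 8 / 64))

    def test_checkerboard_only_w7(self):
        img = (np.indices((8, 8)).sum(0) % 2 * 255).astype(np.uint8)
        q = quadtree_decompose(img)
        assert quadtree_features(q) == (pytest.approx(64 * 1 / 64), 0.0, 0.0, 0.0)


class TestExtractFeatureVector:
    def test_constant_image_composition(self):
        fv = extract_feature_vector(np.full((8, 8), 40, dtype=np.uint8))
        assert fv.w2 == 40.0
        assert fv.w3 == 0.0
        assert fv.w4 == 40.0
        assert fv.w6 == 1.0
        assert (fv.w7, fv.w8, fv.w9) == (0.0, 0.0, 0.0)
        assert fv.w10 == pytest.approx(0.125)

    def test_deterministic(self, random_image):
        a = extract_feature_vector(random_image).to_array()
        b = extract_feature_vector(random_image).to_array()
        np.testing.assert_array_equal(a, b)

    def test_oracles_hold_on_random_image(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        fv = extract_feature_vector(img)
        assert fv.w1 == pytest.approx(sum_of_squares(img), rel=1e-10)
        q = quadtree_decompose(img)
        assert quadtree_area(q.counts) == q.side**2

    def test_features_see_only_the_crop(self, rng):
        from thyrotex.image_io import ROIRect, crop_roi

        inner = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        padded = np.pad(inner, 3, mode="constant", constant_values=255)
        cropped = crop_roi(padded, ROIRect(4, 4, 16, 16))
        np.testing.assert_array_equal(
            extract_feature_vector(cropped).to_array(),
            extract_feature_vector(inner).to_array(),
        )

    def test_too_small_roi_rejected(self):
        with pytest.raises(DegenerateInputError):
            extract_feature_vector(np.zeros((7, 12), dtype=np.uint8))

    def test_one_based_indexing_access(self, random_image):
        fv = extract_feature_vector(random_image)
        assert fv[1] == fv.w1
        assert fv[10] == fv.w10
        with pytest.raises(IndexError):
            fv[0]

    def test_feature_table_layout(self, rng):
        imgs = [rng.integers(0, 256, size=(8, 8)).astype(np.uint8) for _ in range(3)]
        df = feature_table(imgs, labels=[0, 1, 0], ids=["a", "b", "c"])
        assert list(df.columns) == ["image_id", "class_label", *FEATURE_NAMES]
        assert len(df) == 3
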