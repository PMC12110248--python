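import numpy as np
import pytest

from meiboscan.config import PreprocessConfig
from meiboscan.errors import InvalidMaskError
from meiboscan.preprocess import (
    black_out_dark,
    center_histogram,
    close_gray,
    detect_reflections,
    enhance_local_contrast,
    equalize_global,
    fill_reflections,
    preprocess_pipeline,
    stretch_global,
)


def full_mask(img):
    return np.ones_like(img, dtype=np.uint8)


class TestCenterHistogram:
    def test_already_centered_unchanged(self):
        img = np.full((20, 20), 100, dtype=np.uint8)
        out = center_histogram(img, full_mask(img))
        assert np.array_equal(out, img)

    def test_dark_uniform_shifted_to_target(self):
        img = np.full((20, 20), 40, dtype=np.uint8)
        out = center_histogram(img, full_mask(img))
        assert np.all(out == 100)

    def test_mean_at_target_from_extremes(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 200  # mean 100
        out = center_histogram(img, full_mask(img))
        assert np.array_equal(out, img)

    def test_bright_image_passes_through(self):
        img = np.full((10, 10), 180, dtype=np.uint8)
        out = center_histogram(img, full_mask(img), only_dark=True)
        assert np.array_equal(out, img)

    def test_foreground_mean_within_tolerance(self):
        rng = np.random.default_rng(0)
        img = rng.integers(20, 80, size=(50, 50)).astype(np.uint8)
        mask = np.zeros_like(img)
        mask[10:40, 10:40] = 1
        out = center_histogram(img, mask)
        assert abs(float(out[mask > 0].mean()) - 100) <= 1.0

    def test_empty_mask_raises(self):
        img = np.full((5, 5), 40, dtype=np.uint8)
        with pytest.raises(InvalidMaskError):
            center_histogram(img, np.zeros_like(img))


class TestReflections:
    def test_no_saturated_pixels_empty(self):
        img = np.full((30, 30), 80, dtype=np.uint8)
        assert len(detect_reflections(img)) == 0

    def test_single_block_one_component(self):
        img = np.full((40, 40), 80, dtype=np.uint8)
        img[10:15, 20:25] = 255
        comps = detect_reflections(img)
        assert len(comps) == 1
        assert comps.n_pixels == 25

    def test_two_separated_blocks(self):
        img = np.full((40, 40), 80, dtype=np.uint8)
        img[5:8, 5:8] = 255
        img[20:23, 20:23] = 255
        assert len(detect_reflections(img)) == 2

    def test_fill_empty_set_identity(self):
        img = np.full((10, 10), 90, dtype=np.uint8)
        out = fill_reflections(img, [])
        assert np.array_equal(out, img)

    def test_fill_with_contour_mean(self):
        img = np.full((20, 20), 80, dtype=np.uint8)
        img[8:11, 8:11] = 255
        comps = detect_reflections(img)
        out = fill_reflections(img, comps)
        assert np.all(out[8:11, 8:11] == 80)
        assert np.array_equal(out, np.full((20, 20), 80))

    def test_fill_mixed_contour_mean(self):
        # ring half 60 / half 100 -> fill 80
        img = np.full((7, 7), 60, dtype=np.uint8)
        img[4:, :] = 100
        img[2:4, 2:4] = 255  # 2x2 block; ring rows 1-4 mix of 60/100
        comps = detect_reflections(img)
        out = fill_reflections(img, comps)
        ring_vals = []
        for r in range(1, 5):
            for c in range(1, 5):
                if not (2 <= r < 4 and 2 <= c < 4):
                    ring_vals.append(img[r, c])
        expected = int(round(np.mean(ring_vals)))
        assert np.all(out[2:4, 2:4] == expected)

    def test_pipeline_removes_saturated_blob(self, clean_scene):
        img, mask, _ = clean_scene
        img = img.copy()
        img[150:160, 200:210] = 255
        comps = detect_reflections(img)
        filled = fill_reflections(img, comps)
        assert len(detect_reflections(filled)) == 0


class TestBlackOutDark:
    def test_below_threshold_zeroed(self):
        img = np.full((5, 5), 49, dtype=np.uint8)
        assert np.all(black_out_dark(img) == 0)

    def test_at_threshold_kept(self):
        img = np.full((5, 5), 50, dtype=np.uint8)
        assert np.array_equal(black_out_dark(img), img)

    def test_elementwise(self):
        img = np.array([[30, 200], [200, 30]], dtype=np.uint8)
        out = black_out_dark(img)
        assert np.array_equal(out, np.array([[0, 200], [200, 0]]))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        once = black_out_dark(img)
        assert np.array_equal(black_out_dark(once), once)


class TestClahe:
    def test_uniform_unchanged(self):
        img = np.full((100, 100), 120, dtype=np.uint8)
        assert np.array_equal(enhance_local_contrast(img), img)

    def test_output_range(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (200, 300)).astype(np.uint8)
        out = enhance_local_contrast(img)
        assert out.dtype == np.uint8 and out.shape == img.shape

    def test_raises_low_contrast_tiles(self):
        # bimodal but low-contrast image: local contrast must not shrink
        img = np.full((200, 200), 100, dtype=np.uint8)
        img[:, 100:] = 115
        out = enhance_local_contrast(img)
        mid = out.astype(float)
        assert mid[:, 100:].mean() - mid[:, :100].mean() > 15.0


class TestCloseGray:
    def test_uniform_unchanged(self):
        img = np.full((30, 30), 90, dtype=np.uint8)
        assert np.array_equal(close_gray(img), img)

    def test_fills_small_dark_hole(self):
        img = np.full((30, 30), 50, dtype=np.uint8)
        img[5:25, 5:25] = 200
        img[14, 14] = 0
        out = close_gray(img)
        assert out[14, 14] == 200

    def test_idempotent_and_extensive(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        once = close_gray(img)
        assert np.all(once >= img)
        assert np.array_equal(close_gray(once), once)


class TestGlobalEqualization:
    def test_constant_unchanged(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        assert np.array_equal(equalize_global(img), img)

    def test_two_values_span_endpoints(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 20
        img[:, :5] = 10
        out = equalize_global(img)
        # cdf-min rule: lowest occupied bin -> 0, highest -> 255
        assert set(np.unique(out)) == {0, 255}

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (50, 50)).astype(np.uint8)
        out = equalize_global(img)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order].astype(int)) >= 0)

    def test_stretch_full_range_linear(self):
        img = np.full((10, 10), 60, dtype=np.uint8)
        img[0, 0] = 20
        img[0, 1] = 120
        out = stretch_global(img)
        assert out.min() == 0 and out.max() == 255
        assert out[5, 5] == int(round((60 - 20) * 255 / 100))


class TestPipeline:
    def test_dimensions_and_determinism(self, clean_scene):
        img, mask, _ = clean_scene
        a = preprocess_pipeline(img, mask)
        b = preprocess_pipeline(img, mask)
        assert a.shape == img.shape
        assert np.array_equal(a, b)

    def test_noop_stages_compose(self):
        # mean-100 stripe image, nothing saturated: centering and the
        # reflection stage must both be identities
        img = np.full((80, 120), 60, dtype=np.uint8)
        img[:, 40:60] = 140
        img[:, 80:100] = 140  # mean == 100
        mask = np.ones_like(img)
        cfg_all = PreprocessConfig()
        cfg_skip = PreprocessConfig(enable_center=False, enable_reflections=False)
        assert np.array_equal(
            preprocess_pipeline(img, mask, cfg_all),
            preprocess_pipeline(img, mask, cfg_skip),
        )

    def test_info_counts_filled_pixels(self, clean_scene):
        img, mask, _ = clean_scene
        img = img.copy()
        img[150:155, 200:205] = 255
        _, info = preprocess_pipeline(img, mask, with_info=True)
        assert info.n_reflection_components == 1
        assert info.n_reflection_pixels == 25

    def test_mismatched_mask_raises(self):
        with pytest.raises(InvalidMaskError):
            preprocess_pipeline(
                np.zeros((10, 10), dtype=np.uint8),
                np.ones((10, 12), dtype=np.uint8),
            )
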