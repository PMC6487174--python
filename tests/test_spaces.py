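"""Unit and property tests for the multispace reconstruction operators."""

import numpy as np
import pytest

from multispace import (
    ColorImage,
    DegenerateInputError,
    GrayImage,
    SpaceParams,
    glcm_image,
    gradient_image,
    lbp_image,
    reconstruct,
    to_grayscale,
    white_balance,
)
from multispace.spaces import glcm_statistic_map, gradient_magnitude

from .oracles import glcm_stat_oracle, lbp_oracle, sobel_magnitude_oracle


def constant_rgb(r, g, b, h=3, w=3):
    return ColorImage(np.tile(np.array([r, g, b], dtype=np.int64), (h, w, 1)))


class TestWhiteBalance:
    def test_equal_channel_means_is_fixed_point(self, random_rgb):
        img = random_rgb(8, 8)
        # Force equal channel means by using one channel three times.
        pix = np.repeat(img.pixels[:, :, :1], 3, axis=2)
        balanced = white_balance(ColorImage(pix))
        assert np.array_equal(balanced.pixels, pix)

    def test_gray_world_scaling_hand_computed(self):
        # Channel means (100, 200, 100), global mean 400/3: scales (4/3, 2/3, 4/3)
        # map every channel to 133 after rounding.
        balanced = white_balance(constant_rgb(100, 200, 100))
        assert np.array_equal(np.unique(balanced.pixels), [133])

    def test_all_zero_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            white_balance(constant_rgb(0, 120, 80))

    def test_output_in_range_and_shape_preserved(self, random_rgb):
        img = random_rgb(16, 12)
        out = white_balance(img)
        assert out.pixels.shape == img.pixels.shape
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((255, 0, 0), 76), ((0, 255, 0), 150), ((77, 77, 77), 77)],
    )
    def test_luminance_closed_forms(self, rgb, expected):
        gray = to_grayscale(constant_rgb(*rgb))
        assert np.array_equal(np.unique(gray.pixels), [expected])

    def test_rejects_reconstructed_input(self, random_rgb):
        img = ColorImage(random_rgb(4, 4).pixels, color_space="reconstructed")
        with pytest.raises(ValueError):
            to_grayscale(img)


class TestGradient:
    def test_constant_image_is_zero(self):
        out = gradient_image(GrayImage(np.full((6, 7), 40)))
        assert np.array_equal(np.unique(out.pixels), [0])

    def test_vertical_step_edge_localized(self):
        pix = np.zeros((5, 5), dtype=np.int64)
        pix[:, 3:] = 200
        raw = gradient_magnitude(GrayImage(pix))
        oracle = sobel_magnitude_oracle(pix)
        np.testing.assert_allclose(raw, oracle, atol=1e-9)
        # Response confined to the two columns adjacent to the step.
        assert np.all(raw[:, [2, 3]] > 0)
        assert np.all(raw[:, [0, 1, 4]] == 0)

    def test_transpose_symmetry(self, random_gray):
        img = random_gray()
        out = gradient_image(img)
        out_t = gradient_image(GrayImage(img.pixels.T))
        assert np.array_equal(out.pixels.T, out_t.pixels)

    def test_matches_bruteforce_oracle_on_random_images(self, rng):
        for _ in range(5):
            pix = rng.integers(0, 256, size=(9, 9))
            np.testing.assert_allclose(
                gradient_magnitude(GrayImage(pix)), sobel_magnitude_oracle(pix), atol=1e-6
            )


class TestGlcm:
    def test_constant_contrast_zero_energy_full(self):
        img = GrayImage(np.full((8, 8), 100))
        assert np.array_equal(np.unique(glcm_image(img).pixels), [0])
        energy = glcm_image(img, SpaceParams(glcm_statistic="energy"))
        assert np.array_equal(np.unique(energy.pixels), [255])

    def test_checkerboard_center_contrast_is_one(self):
        # Two-level checkerboard, offset (0,1): all horizontal pairs are
        # (0,1)/(1,0), so the raw contrast is exactly 1 before rescaling.
        pix = (np.indices((9, 9)).sum(axis=0) % 2) * 255
        p = SpaceParams(glcm_levels=2, glcm_window=7)
        raw = glcm_statistic_map(GrayImage(pix.astype(np.int64)), p)
        assert raw[4, 4] == pytest.approx(1.0)

    @pytest.mark.parametrize("stat", ["contrast", "energy", "homogeneity"])
    def test_matches_bruteforce_oracle(self, stat, rng):
        pix = rng.integers(0, 256, size=(9, 9))
        p = SpaceParams(glcm_levels=4, glcm_window=5, glcm_statistic=stat)
        got = glcm_statistic_map(GrayImage(pix), p)
        expected = glcm_stat_oracle(pix, levels=4, window=5, offset=(0, 1), stat=stat)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    @pytest.mark.parametrize("offset", [(1, 0), (1, 1), (1, -1)])
    def test_matches_oracle_at_other_offsets(self, offset, rng):
        pix = rng.integers(0, 256, size=(9, 9))
        p = SpaceParams(glcm_levels=4, glcm_window=5, glcm_offset=offset)
        got = glcm_statistic_map(GrayImage(pix), p)
        expected = glcm_stat_oracle(pix, levels=4, window=5, offset=offset, stat="contrast")
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            glcm_image(GrayImage(np.zeros((5, 5), dtype=np.int64)), SpaceParams(glcm_window=7))


class TestLbp:
    def test_constant_image_all_255(self):
        out = lbp_image(GrayImage(np.full((5, 5), 7)))
        assert np.array_equal(np.unique(out.pixels), [255])

    def test_isolated_peak_code_zero(self):
        pix = np.zeros((5, 5), dtype=np.int64)
        pix[2, 2] = 255
        assert lbp_image(GrayImage(pix)).pixels[2, 2] == 0

    def test_hand_evaluated_bit_pattern(self):
        # Center 5, clockwise-from-top-left neighbors (1,2,3,6,9,8,7,4):
        # bits (0,0,0,1,1,1,1,0) MSB-first = 0b00011110 = 30.
        m = GrayImage(np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=np.int64))
        assert lbp_image(m).pixels[1, 1] == 30

    def test_matches_bruteforce_oracle(self, rng):
        pix = rng.integers(0, 256, size=(9, 9))
        assert np.array_equal(lbp_image(GrayImage(pix)).pixels, lbp_oracle(pix))


class TestReconstruct:
    def test_channels_match_component_operators(self, random_rgb):
        img = random_rgb(16, 16)
        p = SpaceParams()
        out = reconstruct(img, p)
        gray = to_grayscale(white_balance(img))
        assert out.color_space == "reconstructed"
        assert np.array_equal(out.pixels[:, :, 0], gradient_image(gray).pixels)
        assert np.array_equal(out.pixels[:, :, 1], glcm_image(gray, p).pixels)
        assert np.array_equal(out.pixels[:, :, 2], lbp_image(gray).pixels)

    def test_constant_image_channel_extremes(self):
        out = reconstruct(constant_rgb(150, 150, 150, h=8, w=8))
        assert np.array_equal(np.unique(out.pixels[:, :, 0]), [0])  # gradient
        assert np.array_equal(np.unique(out.pixels[:, :, 2]), [255])  # LBP

    def test_gradient_peaks_on_nucleus_boundary(self):
        # Single dark disc on a bright field: the Sobel channel must attain
        # its maximum on the boundary ring, never inside the disc or far out.
        yy, xx = np.mgrid[0:64, 0:64]
        radius = np.hypot(yy - 32.0, xx - 32.0)
        pix = np.where(radius[..., None] <= 12, 70, 220).astype(np.int64)
        pix = np.repeat(pix, 3, axis=2)
        out = reconstruct(ColorImage(pix))
        peak_positions = np.argwhere(out.pixels[:, :, 0] == out.pixels[:, :, 0].max())
        peak_r = radius[peak_positions[:, 0], peak_positions[:, 1]]
        assert np.all(np.abs(peak_r - 12) <= 2)

    def test_deterministic(self, random_rgb):
        img = random_rgb(16, 16)
        a, b = reconstruct(img), reconstruct(img)
        assert np.array_equal(a.pixels, b.pixels)

    def test_shape_preserved_and_in_range(self, random_rgb):
        img = random_rgb(20, 12)
        out = reconstruct(img)
        assert out.pixels.shape == img.pixels.shape
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255
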