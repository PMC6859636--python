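import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rootpcj import preprocess as pp
from _oracles import component_size_filter, otsu_exhaustive

small_masks = arrays(np.uint8, (12, 12), elements=st.integers(0, 1))


class TestGrayscale:
    def test_equal_channels_collapse_to_value(self):
        img = np.dstack([np.full((4, 5), 77)] * 3)
        assert np.allclose(pp.to_grayscale(img), 77)

    def test_idempotent_on_gray(self):
        g = np.arange(12).reshape(3, 4)
        assert np.array_equal(pp.to_grayscale(g), g)

    def test_pure_red_matches_per_pixel_luma(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255
        expected = 0.299 * 255  # brute-force per-pixel conversion
        assert np.allclose(pp.to_grayscale(img), expected)

    def test_empty_image_rejected(self):
        with pytest.raises(pp.InputError):
            pp.to_grayscale(np.zeros((0, 3)))


class TestDenoise:
    @pytest.mark.parametrize("method", ["median", "gaussian"])
    def test_constant_image_unchanged(self, method):
        g = np.full((6, 6), 42.0)
        assert np.allclose(pp.denoise(g, method, 3), 42.0)

    def test_median_removes_isolated_impulse(self):
        g = np.zeros((7, 7))
        g[3, 3] = 200
        assert pp.denoise(g, "median", 3)[3, 3] == 0

    def test_gaussian_impulse_reproduces_kernel(self):
        g = np.zeros((9, 9))
        g[4, 4] = 1.0
        out = pp.denoise(g, "gaussian", 3)
        # direct oracle: the impulse response is the normalized sampled
        # gaussian kernel (sigma = window/6 = 0.5, 3x3 support)
        w1 = np.exp(-np.arange(-1, 2) ** 2 / (2 * 0.5 ** 2))
        kernel = np.outer(w1, w1)
        kernel /= kernel.sum()
        assert np.allclose(out[3:6, 3:6], kernel)
        assert np.isclose(out.sum(), 1.0)

    def test_even_window_rejected(self):
        with pytest.raises(pp.ConfigError):
            pp.denoise(np.zeros((4, 4)), "median", 4)


class TestBinarize:
    def test_all_zero_fixed_threshold(self):
        assert pp.binarize(np.zeros((5, 5)), 128).sum() == 0

    def test_automatic_threshold_separates_two_levels(self, rng):
        g = rng.choice([40.0, 200.0], size=(16, 16))
        t = otsu_exhaustive(g)
        mask = pp.binarize(g)
        assert np.array_equal(mask, (g > t).astype(np.uint8))
        assert set(np.unique(mask)) <= {0, 1}

    def test_constant_image_automatic_no_crash(self):
        out = pp.binarize(np.full((4, 4), 9.0))
        assert out.sum() in (0, 16)

    def test_out_of_range_threshold(self):
        with pytest.raises(pp.ConfigError):
            pp.binarize(np.zeros((3, 3)), 300)


class TestFloodBackground:
    def test_enclosed_hole_filled(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[1:6, 1:6] = 1
        mask[3, 3] = 0  # hole
        out = pp.flood_background(mask, (0, 0), fill_holes=True)
        assert out[3, 3] == 1
        assert out.sum() == mask.sum() + 1

    def test_no_foreground_unchanged(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        assert np.array_equal(pp.flood_background(mask, (2, 2)), mask)

    def test_hole_filling_off_is_identity(self):
        mask = np.zeros((7, 7), dtype=np.uint8)
        mask[1:6, 1:6] = 1
        mask[3, 3] = 0
        assert np.array_equal(
            pp.flood_background(mask, (0, 0), fill_holes=False), mask)

    def test_seed_on_foreground_rejected(self):
        mask = np.ones((3, 3), dtype=np.uint8)
        with pytest.raises(pp.InputError):
            pp.flood_background(mask, (1, 1))


class TestRemoveSpecks:
    def test_single_pixel_removed(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 2] = 1
        assert pp.remove_specks(mask, 2).sum() == 0

    def test_exact_min_px_retained(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[2, 1:4] = 1
        assert pp.remove_specks(mask, 3).sum() == 3

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(mask=small_masks, min_px=st.integers(1, 6))
    def test_never_grows_and_idempotent(self, mask, min_px):
        out = pp.remove_specks(mask, min_px)
        assert out.sum() <= mask.sum()
        assert (mask[out > 0] == 1).all()
        assert np.array_equal(pp.remove_specks(out, min_px), out)

    def test_matches_component_oracle_on_random_masks(self, rng):
        for _ in range(100):
            mask = (rng.random((32, 32)) < 0.25).astype(np.uint8)
            got = pp.remove_specks(mask, 4)
            want = component_size_filter(mask, 4)
            assert np.array_equal(got, want)
            assert got.sum() <= mask.sum()


class TestEdgeContinuity:
    def test_five_pixel_run_triggers(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:7, 0] = 1
        flags = pp.edge_continuity(mask)
        assert flags == {"top": False, "bottom": False, "left": True,
                         "right": False}

    def test_exactly_four_does_not_trigger(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:6, 0] = 1
        assert not pp.edge_continuity(mask)["left"]

    def test_empty_mask_all_false(self):
        assert not any(pp.edge_continuity(np.zeros((6, 6))).values())

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(mask=small_masks)
    def test_rotation_permutes_sides(self, mask):
        f0 = pp.edge_continuity(mask)
        f90 = pp.edge_continuity(np.rot90(mask))  # top <- right, etc.
        assert f90["left"] == f0["top"]
        assert f90["bottom"] == f0["left"]
        assert f90["right"] == f0["bottom"]
        assert f90["top"] == f0["right"]
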