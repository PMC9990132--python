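import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roicrop import (CropSpec, Grid2D, SliceSample, center_crop,
                     extract_window, n_random_samples, plan_resample,
                     random_crop, resample_mask, roi_stats, stride_crop,
                     stride_grid)
from .conftest import disk_mask


class TestNRandomSamples:
    def test_worked_example(self):
        # Nroi=10,000 and a 128x128 crop: ratio 0.610, factor 10 -> 6
        assert 10_000 / (128 * 128) == pytest.approx(0.610, abs=5e-4)
        assert n_random_samples(10_000, 128 * 128, 10) == 6

    def test_empty_roi(self):
        assert n_random_samples(0, 4096, 12) == 0

    def test_ratio_exactly_one(self):
        assert n_random_samples(16_384, 128 * 128, 1) == 1

    @pytest.mark.parametrize("args", [(100, 0, 10), (100, 4096, 0.0),
                                      (-1, 4096, 10)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            n_random_samples(*args)

    @settings(derandomize=True, max_examples=100)
    @given(n_roi=st.integers(0, 10 ** 6), n_crop=st.integers(1, 10 ** 5),
           c=st.floats(0.1, 50, allow_nan=False))
    def test_monotone_and_doubling(self, n_roi, n_crop, c):
        base = n_random_samples(n_roi, n_crop, c)
        assert n_random_samples(n_roi + 1000, n_crop, c) >= base
        assert n_random_samples(n_roi, n_crop, 2 * c) >= 2 * base


class TestExtractWindow:
    def test_full_raster_identity(self):
        r = np.arange(20.0).reshape(4, 5)
        win = extract_window(r, (0, 0), 4, 5)
        assert np.array_equal(win.patch, r)
        assert win.origin_rc == (0, 0) and not win.padded

    def test_negative_origin_clamped(self):
        r = np.arange(100.0).reshape(10, 10)
        win = extract_window(r, (-3, -7), 4, 4)
        assert win.origin_rc == (0, 0)
        assert np.array_equal(win.patch, r[:4, :4])

    def test_overhanging_origin_clamped(self):
        r = np.arange(100.0).reshape(10, 10)
        win = extract_window(r, (9, 9), 4, 4)
        assert win.origin_rc == (6, 6)

    def test_small_raster_padded_and_centered(self):
        r = np.ones((50, 50))
        win = extract_window(r, (0, 0), 64, 64)
        assert win.padded
        assert win.patch.shape == (64, 64)
        # content centered: pad 7 on top/left, 7 on bottom/right
        assert win.patch[7:57, 7:57].sum() == 2500
        assert win.patch.sum() == 2500


def _spec(out=128, spacing=0.5, **kw):
    return CropSpec(out, out, (spacing, spacing), **kw)


class TestCenterCrop:
    def test_symmetric_roi_origin_is_centroid_minus_half(self, generous_slice):
        sample, mask = generous_slice
        roi = roi_stats(mask, sample.grid)
        out = center_crop(sample, mask, _spec(), roi)
        assert len(out) == 1
        # centroid 191.5 rounds half-away to 192; origin = 192 - 128//2
        assert out[0].origin_rc == (192 - 64, 192 - 64)
        assert out[0].patch.shape == (128, 128)

    def test_edge_roi_window_clamped_inside(self, grid_05):
        mask = np.zeros(grid_05.shape, np.uint8)
        mask[:40, :40] = 1  # corner ROI
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape),
                             gland_mask=mask)
        out = center_crop(sample, mask, _spec())
        assert len(out) == 1
        assert out[0].origin_rc == (0, 0)
        assert not out[0].padded

    def test_empty_roi_gives_empty_list(self, grid_05):
        mask = np.zeros(grid_05.shape, np.uint8)
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape))
        assert center_crop(sample, mask, _spec()) == []

    def test_area_below_threshold_rejected(self, generous_slice):
        sample, mask = generous_slice
        spec = _spec(c_min_area_mm2=1e6)
        assert center_crop(sample, mask, spec) == []


class TestRandomCrop:
    def test_worked_example_emits_exactly_six(self, generous_slice):
        sample, mask = generous_slice
        spec = _spec(c_random=10.0)
        out = random_crop(sample, mask, spec, seed=123)
        assert len(out) == 6

    def test_patches_in_image_and_centers_in_roi(self, generous_slice):
        sample, mask = generous_slice
        spec = _spec(c_random=10.0)
        out = random_crop(sample, mask, spec, seed=9)
        h, w = sample.grid.shape
        for res in out:
            r0, c0 = res.origin_rc
            assert 0 <= r0 <= h - 128 and 0 <= c0 <= w - 128
            assert not res.padded
            # pre-clamp center lay in the ROI; clamped window must still
            # intersect it
            assert res.in_crop_roi_area_mm2 > 0

    def test_same_seed_is_bit_identical(self, generous_slice):
        sample, mask = generous_slice
        spec = _spec(c_random=10.0)
        a = random_crop(sample, mask, spec, seed=77)
        b = random_crop(sample, mask, spec, seed=77)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.origin_rc == y.origin_rc
            assert np.array_equal(x.patch, y.patch)

    def test_empty_roi(self, grid_05):
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape))
        assert random_crop(sample, np.zeros(grid_05.shape, np.uint8),
                           _spec(), seed=0) == []


def _brute_force_count(box_len, win, stride):
    """Independent oracle: step through the rounded box and count fits."""
    n, pos = 0, 0
    while pos + win <= box_len:
        n += 1
        pos += stride
    return max(1, n)


class TestStrideGrid:
    def test_example_70x90_box(self, grid_05):
        mask = np.zeros(grid_05.shape, np.uint8)
        mask[10:80, 20:110] = 1  # tight box 70 x 90
        roi = roi_stats(mask, grid_05)
        spec = CropSpec(64, 64, (0.5, 0.5), c_stride=32)
        sg = stride_grid(roi, spec, grid_05)
        assert (sg.box.height, sg.box.width) == (96, 96)
        assert (sg.n_rows, sg.n_cols) == (2, 2)
        assert len(sg.origins) == 4
        assert sg.origins[0] == (10, 20)
        assert sg.origins[-1] == (10 + 32, 20 + 32)

    def test_box_smaller_than_window_gives_one_origin(self, grid_05):
        mask = np.zeros(grid_05.shape, np.uint8)
        mask[5:25, 5:25] = 1
        roi = roi_stats(mask, grid_05)
        sg = stride_grid(roi, CropSpec(64, 64, (0.5, 0.5), c_stride=32),
                         grid_05)
        assert len(sg.origins) == 1
        assert sg.origins[0] == (5, 5)

    def test_zero_slack_single_origin(self, grid_05):
        mask = np.zeros(grid_05.shape, np.uint8)
        mask[10:74, 10:74] = 1  # 64x64 tight box == window
        roi = roi_stats(mask, grid_05)
        sg = stride_grid(roi, CropSpec(64, 64, (0.5, 0.5), c_stride=32),
                         grid_05)
        assert sg.origins == ((10, 10),)

    def test_counts_match_brute_force_on_random_boxes(self):
        rng = np.random.default_rng(1234)
        g = Grid2D(2000, 2000, 0.5, 0.5)
        for _ in range(300):
            stride = int(rng.choice([8, 16, 32, 64]))
            h = int(rng.integers(1, 400))
            w = int(rng.integers(1, 400))
            win_h = stride * int(rng.integers(1, 8))
            win_w = stride * int(rng.integers(1, 8))
            mask = np.zeros(g.shape, np.uint8)
            mask[100:100 + h, 100:100 + w] = 1
            roi = roi_stats(mask, g)
            spec = CropSpec(win_h, win_w, (0.5, 0.5), c_stride=stride)
            sg = stride_grid(roi, spec, g)
            import math
            h_box = math.ceil(h / stride) * stride
            w_box = math.ceil(w / stride) * stride
            expected = (_brute_force_count(h_box, win_h, stride)
                        * _brute_force_count(w_box, win_w, stride))
            assert len(sg.origins) == expected


class TestStrideCrop:
    def test_windows_cover_all_roi_pixels(self, grid_05):
        mask = disk_mask(grid_05.shape, (180.0, 150.0), 60)
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape),
                             gland_mask=mask)
        spec = CropSpec(64, 64, (0.5, 0.5), c_stride=32)
        roi = roi_stats(mask, grid_05)
        sg = stride_grid(roi, spec, grid_05)
        covered = np.zeros(grid_05.shape, bool)
        for (r, c) in sg.origins:
            r = min(max(r, 0), grid_05.height_px - 64)
            c = min(max(c, 0), grid_05.width_px - 64)
            covered[r:r + 64, c:c + 64] = True
        assert covered[mask > 0].all()

    def test_emitted_patches_pass_filter(self, grid_05):
        mask = disk_mask(grid_05.shape, (180.0, 150.0), 40)
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape))
        spec = CropSpec(64, 64, (0.5, 0.5), c_stride=32, c_min_area_mm2=100.0)
        out = stride_crop(sample, mask, spec)
        assert out  # the disk comfortably exceeds 1 cm^2 in central windows
        for res in out:
            assert res.in_crop_roi_area_mm2 > 100.0
            assert res.patch.shape == (64, 64)

    def test_empty_mask_gives_empty_list(self, grid_05):
        sample = SliceSample(grid=grid_05, intensity=np.zeros(grid_05.shape))
        assert stride_crop(sample, np.zeros(grid_05.shape, np.uint8),
                           _spec()) == []


class TestBudgetSpacingInvariance:
    def test_budget_stable_across_spacings(self):
        """The random budget is spacing-invariant when ROI physical area
        and crop physical size are held fixed (floor effects aside)."""
        src = Grid2D(256, 256, 0.5, 0.5)
        mask = disk_mask(src.shape, (128.0, 128.0), 40)  # 20 mm radius
        crop_mm = 32.0
        budgets = []
        for sp in (0.2, 0.25, 0.4, 0.5):
            plan = plan_resample(src, (sp, sp))
            m = resample_mask(mask, plan)
            n_roi = int(m.sum())
            out_px = round(crop_mm / sp)
            budgets.append(n_random_samples(n_roi, out_px * out_px, 12.0))
        assert max(budgets) - min(budgets) <= 1
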