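import numpy as np
import pytest

from vmi.segmentation import (
    SegmentationParams,
    apply_exclusion_mask,
    binarize,
    cavity_mask_from_foreground,
    enhance_contrast_3d,
    invert_slices,
    rescale_intensity_3d,
    rolling_ball_background,
    rolling_ball_subtract,
    segment_vasculature,
)
from vmi.volume_io import ImageVolume, VesselMask

from oracles import brute_force_rolling_ball_background

ISO = (10.0, 10.0, 10.0)


def vol(arr, spacing=ISO, **kw):
    return ImageVolume(np.asarray(arr), spacing, **kw)


class TestRescaleIntensity:
    def test_two_values_map_to_endpoints(self):
        v = vol(np.array([10, 30]).reshape(1, 1, 2))
        out = rescale_intensity_3d(v)
        np.testing.assert_array_equal(out.voxels.ravel(), [0, 65535])

    def test_midpoint_rounds_half_up(self):
        # (20-10)/20 * 65535 = 32767.5 -> 32768
        v = vol(np.array([10, 20, 30]).reshape(1, 1, 3))
        out = rescale_intensity_3d(v)
        np.testing.assert_array_equal(out.voxels.ravel(), [0, 32768, 65535])

    def test_constant_maps_to_zero(self):
        out = rescale_intensity_3d(vol(np.full((2, 3, 4), 123)))
        assert out.voxels.max() == 0

    def test_whole_volume_not_per_slice(self):
        arr = np.zeros((2, 1, 2))
        arr[0] = [[0, 100]]
        arr[1] = [[0, 50]]  # slice max differs from global max
        out = rescale_intensity_3d(vol(arr))
        assert out.voxels[1, 0, 1] == round(50 / 100 * 65535)

    def test_idempotent(self, rng):
        v = vol(rng.integers(0, 65535, (3, 8, 8)).astype(np.uint16))
        once = rescale_intensity_3d(v)
        twice = rescale_intensity_3d(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)


class TestInvertSlices:
    def test_endpoints(self):
        v = vol(np.array([0, 65535]).reshape(1, 1, 2).astype(np.uint16))
        out = invert_slices(v)
        np.testing.assert_array_equal(out.voxels.ravel(), [65535, 0])

    def test_involution(self, rng):
        v = vol(rng.integers(0, 65536, (4, 6, 6)).astype(np.uint16))
        np.testing.assert_array_equal(invert_slices(invert_slices(v)).voxels, v.voxels)

    def test_requires_bit_range(self):
        v = vol(np.full((1, 1, 1), 300.0), **{"bit_depth": 8})
        with pytest.raises(ValueError, match="rescale"):
            invert_slices(v)


class TestRollingBall:
    def test_constant_slice_gives_zero(self):
        v = vol(np.full((2, 16, 16), 500.0))
        out = rolling_ball_subtract(v, 50.0)
        assert np.all(out.voxels == 0)

    def test_single_bright_pixel_preserved(self):
        sl = np.zeros((64, 64))
        sl[32, 32] = 1000.0
        bg = rolling_ball_background(sl, 10)
        residual = sl - bg
        assert abs(residual[32, 32] - 1000.0) <= 1.0

    def test_ramp_removed_ridge_preserved(self):
        yy, xx = np.mgrid[0:64, 0:64]
        ramp = 10.0 * yy + 5.0 * xx
        ridge = np.zeros((64, 64))
        ridge[:, 30:33] = 5000.0
        sl = ramp + ridge
        bg = rolling_ball_background(sl, 20)
        residual = np.clip(sl - bg, 0, None)
        off_ridge = residual[:, :28]
        assert off_ridge.max() < 0.02 * 5000.0
        assert residual[32, 31] > 0.9 * 5000.0

    def test_radius_below_one_pixel_errors(self):
        v = vol(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError, match="below one pixel"):
            rolling_ball_subtract(v, 5.0)  # 5 µm at 10 µm spacing

    def test_nonnegative_and_bounded(self, rng):
        v = vol(rng.integers(0, 65535, (3, 24, 24)).astype(np.float64))
        out = rolling_ball_subtract(v, 30.0)
        assert out.voxels.min() >= 0
        for z in range(3):
            assert out.voxels[z].max() <= v.voxels[z].max()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sl = rng.integers(0, 65535, (32, 32)).astype(np.float64)
        radius = [5, 10, 20][seed % 3]
        bg_fast = rolling_ball_background(sl, radius)
        bg_brute = brute_force_rolling_ball_background(sl, radius)
        assert np.max(np.abs(bg_fast - bg_brute)) <= 1.0


class TestEnhanceContrast:
    def test_full_range_output(self, rng):
        v = vol(rng.integers(100, 5000, (2, 8, 8)).astype(np.float64))
        out = enhance_contrast_3d(v)
        assert out.voxels.min() == 0
        assert out.voxels.max() == 65535

    def test_constant_gives_zeros(self):
        assert enhance_contrast_3d(vol(np.full((2, 2, 2), 9.0))).voxels.max() == 0


class TestExclusionMask:
    def test_empty_exclude_identity(self, rng):
        m = VesselMask(rng.random((4, 4, 4)) > 0.5, ISO)
        empty = VesselMask(np.zeros((4, 4, 4), bool), ISO)
        out, frac = apply_exclusion_mask(m, empty)
        np.testing.assert_array_equal(out.voxels, m.voxels)
        assert frac == 0.0

    def test_full_exclude_annihilates(self, rng):
        m = VesselMask(rng.random((4, 4, 4)) > 0.2, ISO)
        full = VesselMask(np.ones((4, 4, 4), bool), ISO)
        out, frac = apply_exclusion_mask(m, full)
        assert out.count() == 0
        assert frac == 1.0

    def test_partial_exclusion_fraction(self):
        m = np.zeros((1, 10, 10), bool)
        m[0, :10, :10].flat[:100] = True  # 100 true voxels
        ex = np.zeros((1, 10, 10), bool)
        ex.flat[:30] = True  # covers 30 of them
        out, frac = apply_exclusion_mask(VesselMask(m, ISO), VesselMask(ex, ISO))
        assert out.count() == 70
        assert frac == pytest.approx(0.30)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            apply_exclusion_mask(
                VesselMask(np.zeros((2, 2, 2), bool), ISO),
                VesselMask(np.zeros((2, 2, 3), bool), ISO),
            )


class TestCavityMask:
    def test_dark_cavity_detected(self):
        arr = np.full((8, 16, 16), 50000.0)
        arr[2:6, 4:12, 4:12] = 0.0
        mask = cavity_mask_from_foreground(vol(arr))
        assert mask.voxels[4, 8, 8]
        assert not mask.voxels[0, 0, 0]

    def test_uniform_bright_gives_empty(self):
        mask = cavity_mask_from_foreground(vol(np.full((4, 8, 8), 60000.0)))
        assert mask.count() == 0

    def test_size_floor_keeps_only_large_cavity(self):
        arr = np.full((10, 20, 20), 50000.0)
        arr[1:7, 2:8, 2:8] = 0.0  # large cavity, 216 voxels
        arr[8, 15, 15] = 0.0  # 1-voxel speck
        mask = cavity_mask_from_foreground(vol(arr), threshold=1000.0, min_object_voxels=10)
        from scipy import ndimage as ndi

        _, n = ndi.label(mask.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert not mask.voxels[8, 15, 15]

    def test_threshold_outside_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            cavity_mask_from_foreground(vol(np.full((2, 2, 2), 10.0)), threshold=99.0)


class TestBinarize:
    def params(self, **kw):
        defaults = dict(rolling_ball_radius=50.0)
        defaults.update(kw)
        return SegmentationParams(**defaults)

    def test_bimodal_separation(self, rng):
        arr = np.zeros((8, 16, 16))
        arr[2:4, 4:8, 4:8] = 60000.0
        arr += rng.normal(0, 10, arr.shape) ** 2  # small positive noise
        mask = binarize(vol(arr), self.params())
        assert mask.voxels[3, 5, 5]
        assert not mask.voxels[0, 0, 0]

    def test_min_object_removes_speck(self):
        arr = np.zeros((10, 16, 16))
        arr[2:4, 2:6, 2:6] = 60000.0  # 32-voxel block
        arr[8, 12, 12:17] = 60000.0  # 4-voxel speck
        mask = binarize(vol(arr), self.params(min_object_voxels=10))
        assert mask.voxels[2, 3, 3]
        assert not mask.voxels[8, 12, 12]

    def test_all_zero_gives_empty(self):
        assert binarize(vol(np.zeros((4, 4, 4))), self.params()).count() == 0

    def test_otsu_option_on_balanced_modes(self, rng):
        arr = rng.normal(5000, 100, (8, 16, 16)).clip(0)
        arr[:4] += 50000.0
        mask = binarize(vol(arr), self.params(binarization="otsu"))
        assert mask.voxels[:4].all()
        assert not mask.voxels[4:].any()

    def test_percentile_option(self, rng):
        arr = rng.permutation(np.arange(1000.0)).reshape(10, 10, 10)
        mask = binarize(vol(arr), self.params(binarization="percentile", percentile=90.0))
        assert mask.count() == 100


class TestSegmentVasculature:
    def test_uniform_bright_gives_empty_mask(self):
        v = vol(np.full((8, 32, 32), 30000.0))
        mask = segment_vasculature(v, SegmentationParams(rolling_ball_radius=50.0))
        assert mask.count() == 0

    def test_dark_bright_duality(self):
        from tests_support_phantom import quick_phantom

        v, _ = quick_phantom(seed=11)
        p_dark = SegmentationParams(rolling_ball_radius=50.0, invert=True)
        p_bright = SegmentationParams(rolling_ball_radius=50.0, invert=False)
        pre = invert_slices(rescale_intensity_3d(v))
        m1 = segment_vasculature(v, p_dark)
        m2 = segment_vasculature(pre, p_bright)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_affine_intensity_invariance(self):
        from tests_support_phantom import quick_phantom

        v, _ = quick_phantom(seed=12)
        params = SegmentationParams(rolling_ball_radius=50.0)
        m1 = segment_vasculature(v, params)
        affine = v.with_voxels(2.0 * v.voxels.astype(np.float64) + 100.0)
        m2 = segment_vasculature(affine, params)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_recovers_phantom_mask(self):
        from tests_support_phantom import quick_phantom
        from vmi.metrics import dice

        v, truth = quick_phantom(seed=13)
        mask = segment_vasculature(v, SegmentationParams(rolling_ball_radius=50.0))
        assert dice(mask, truth).dice >= 0.8

    def test_stage_dump(self, tmp_path):
        from tests_support_phantom import quick_phantom

        v, _ = quick_phantom(seed=14)
        segment_vasculature(
            v, SegmentationParams(rolling_ball_radius=50.0), save_stages=tmp_path
        )
        names = {p.name for p in tmp_path.iterdir()}
        assert "stage1_rescaled.tif" in names
        assert "stage5_mask.tif" in names
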