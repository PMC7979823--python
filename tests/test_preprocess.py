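"""Registration, background subtraction, illumination correction, focus
projection and normalization contracts."""

import numpy as np
import pytest
from scipy import ndimage

from melchist.io import ConfigError, ValidationError
from melchist.preprocess import (
    DegenerateCorrelationError,
    PreprocessParams,
    correct_illumination,
    estimate_illumination,
    extended_depth_of_field,
    normalize_image,
    preprocess_run,
    register_cycle,
    subtract_background,
    subtract_secondary,
)
from melchist.synthetic import default_tonsil_like_spec, simulate_run, translate


@pytest.fixture(scope="module")
def textured():
    return np.random.default_rng(0).random((96, 96))


class TestRegistration:
    def test_identity(self, textured):
        shift, registered = register_cycle(textured, textured, 10)
        assert shift == (0, 0)
        np.testing.assert_array_equal(registered, textured)

    def test_known_roll_recovered(self, textured):
        moving = np.roll(textured, (3, -2), axis=(0, 1))
        shift, registered = register_cycle(moving, textured, 10)
        assert shift == (3, -2)
        interior = (slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(registered[interior], textured[interior])

    def test_matches_exhaustive_search(self, textured):
        """Exhaustive correlation over every allowed shift agrees."""
        moving = translate(textured, -4, 6)
        shift, _ = register_cycle(moving, textured, 8)
        best, best_corr = None, -np.inf
        for dr in range(-8, 9):
            for dc in range(-8, 9):
                cand = translate(textured, dr, dc)
                corr = np.corrcoef(cand.ravel(), moving.ravel())[0, 1]
                if corr > best_corr:
                    best, best_corr = (dr, dc), corr
        assert shift == best == (-4, 6)

    def test_tie_break_smallest_l1_then_lexicographic(self):
        # period-4 stripes: shifts (0,-2) and (0,2) correlate identically
        img = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (64, 16))
        moving = np.roll(img, 2, axis=1)
        shift, _ = register_cycle(moving, img, 6)
        assert shift == (0, -2)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateCorrelationError):
            register_cycle(np.ones((64, 64)), np.zeros((64, 64)) + 0.5, 8)

    def test_max_shift_bound(self, textured):
        with pytest.raises(ConfigError):
            register_cycle(textured, textured, 40)


class TestSubtraction:
    def test_pixel_arithmetic(self):
        fluo = np.full((8, 8), 1000.0)
        bleach = np.full((8, 8), 300.0)
        np.testing.assert_array_equal(subtract_background(fluo, bleach), 700.0)

    def test_identical_images_cancel(self):
        img = np.random.default_rng(1).random((16, 16))
        assert subtract_background(img, img).max() == 0.0

    def test_clamped_at_zero(self):
        out = subtract_background(np.full((4, 4), 1000.0), np.full((4, 4), 1200.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            subtract_background(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_secondary_offset_field(self):
        rng = np.random.default_rng(2)
        primary = rng.random((16, 16)) + 0.5
        offset = rng.random((16, 16)) * 0.3
        np.testing.assert_allclose(
            subtract_secondary(primary + offset, offset), primary, atol=1e-12)

    def test_zero_secondary_is_identity(self):
        img = np.random.default_rng(3).random((8, 8))
        np.testing.assert_array_equal(subtract_secondary(img, np.zeros_like(img)), img)


class TestIllumination:
    def test_constant_bleach_gives_flat_field(self):
        field = estimate_illumination(np.full((128, 128), 0.3))
        np.testing.assert_allclose(field, 1.0, atol=1e-9)

    def test_recovers_known_smooth_field(self):
        rr, cc = np.mgrid[0:256, 0:256]
        g = 1 + 0.3 * np.exp(-((rr - 100) ** 2 + (cc - 170) ** 2) / (2 * 120.0**2))
        field = estimate_illumination(0.08 * g)
        assert np.abs(field - g / g.mean()).max() <= 0.02

    def test_floor_clip(self):
        rr, cc = np.mgrid[0:128, 0:128]
        steep = 0.001 + 2.0 * np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * 10.0**2))
        field = estimate_illumination(steep, floor=0.05)
        assert field.min() >= 0.05 - 1e-12

    def test_small_grid_rejected(self):
        with pytest.raises(ConfigError):
            estimate_illumination(np.ones((64, 64)), spline_grid=3)

    def test_correct_flat_field_identity(self):
        img = np.random.default_rng(4).random((32, 32))
        np.testing.assert_array_equal(correct_illumination(img, np.ones_like(img)), img)

    def test_correct_rejects_bad_mean(self):
        with pytest.raises(ValidationError):
            correct_illumination(np.ones((8, 8)), np.full((8, 8), 0.5))

    def test_mean_intensity_preserved_for_mean_one_field(self):
        """Dividing a scene rendered under a mean-1 field by the estimated
        field preserves the mean intensity within 1%."""
        spec = default_tonsil_like_spec(
            13, image_shape=(256, 256), n_cells=36, noise_sd=0.0,
            illumination_amplitude=0.3, max_shift_px=0)
        spec.stage_shifts_px = {}
        run, truth = simulate_run(spec)
        g = truth.illumination_field / truth.illumination_field.mean()
        rec = run.cycles[0]
        field = estimate_illumination(rec.bleach_zstack.mean(axis=0))
        img = truth.scenes[rec.marker.name] * g
        corrected = correct_illumination(img, field)
        assert abs(corrected.mean() - truth.scenes[rec.marker.name].mean()) \
            <= 0.01 * truth.scenes[rec.marker.name].mean()

    def test_background_cv_reduced_fivefold(self):
        """With amplitude >= 0.3, correction shrinks the background
        coefficient of variation to <= 20% of its pre-correction value."""
        spec = default_tonsil_like_spec(
            7, image_shape=(256, 256), n_cells=25, noise_sd=0.0,
            illumination_amplitude=0.35, max_shift_px=0)
        spec.stage_shifts_px = {}
        run, truth = simulate_run(spec)
        b = run.cycles[0].bleach_zstack.mean(axis=0)
        field = estimate_illumination(b)
        bg = ~ndimage.binary_dilation(truth.cell_labels > 0, iterations=12)
        cv = lambda x: x[bg].std() / x[bg].mean()  # noqa: E731
        assert cv(b / field) <= 0.2 * cv(b)


class TestExtendedDepthOfField:
    def test_single_plane_unchanged(self):
        img = np.random.default_rng(5).random((32, 32))
        np.testing.assert_array_equal(extended_depth_of_field(img[None], 5), img)

    def test_identical_planes_tie_to_lowest_z(self):
        img = np.random.default_rng(6).random((32, 32))
        stack = np.stack([img, img, img])
        np.testing.assert_array_equal(extended_depth_of_field(stack, 5), img)

    def test_selects_sharp_plane_per_region(self):
        """Plane 0 sharp left, plane 2 sharp right; output follows."""
        rng = np.random.default_rng(7)
        sharp = rng.random((64, 64))
        blurred = ndimage.gaussian_filter(sharp, 3.0)
        p0 = np.where(np.arange(64)[None, :] < 32, sharp, blurred)
        p2 = np.where(np.arange(64)[None, :] < 32, blurred, sharp)
        p1 = ndimage.gaussian_filter(sharp, 5.0)
        out = extended_depth_of_field(np.stack([p0, p1, p2]), 7)
        w = 7
        np.testing.assert_array_equal(out[:, :32 - w], p0[:, :32 - w])
        np.testing.assert_array_equal(out[:, 32 + w:], p2[:, 32 + w:])

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            extended_depth_of_field(np.zeros((3, 16, 16)), 4)


class TestNormalize:
    def test_constant_image_flattens_to_zero(self):
        params = PreprocessParams(rolling_ball_radius_px=10)
        out = normalize_image(np.full((96, 96), 500.0), params, crop_margin_px=0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_stretch_hits_full_16bit_range(self):
        rng = np.random.default_rng(8)
        img = rng.random((128, 128)) * 100
        out = normalize_image(img, PreprocessParams(), crop_margin_px=4)
        assert out.min() == 0.0
        assert out.max() == 65535.0

    def test_disk_contrast_preserved_after_background_removal(self):
        """A disk on a smooth ramp keeps its contrast within 5%."""
        rr, cc = np.mgrid[0:192, 0:192]
        ramp = 0.3 + 0.2 * (rr / 191.0)
        disk = (rr - 96) ** 2 + (cc - 96) ** 2 <= 12**2
        img = ramp + 0.5 * disk
        params = PreprocessParams(rolling_ball_radius_px=50,
                                  stretch_percentiles=(0.0, 100.0))
        out = normalize_image(img, params, crop_margin_px=0)
        # oracle: perfect background removal leaves a flat 0.5 disk on a zero
        # background, so after the full-range stretch the normalized contrast
        # (disk mean minus background median, over the full range) is 1
        contrast = (out[disk].mean() - np.median(out[~disk])) / 65535.0
        assert abs(contrast - 1.0) <= 0.05

    def test_excessive_crop_rejected(self):
        with pytest.raises(ValidationError, match="crop"):
            normalize_image(np.ones((100, 100)), PreprocessParams(), crop_margin_px=40)


class TestPreprocessRun:
    def test_shifts_recovered_and_shapes_cropped(self, lownoise_scene, lownoise_result):
        _, run, truth = lownoise_scene
        res = lownoise_result
        assert res["shifts"] == truth.shifts
        margin = res["margin"]
        expected_shape = tuple(s - 2 * margin for s in run.geometry.image_shape)
        for img in res["corrected"].values():
            assert img.shape == expected_shape
        assert set(res["corrected"]) == {m.name for m in run.panel}

    def test_outputs_nonnegative(self, lownoise_result):
        for img in lownoise_result["corrected"].values():
            assert img.min() >= 0.0

    def test_clean_run_images_match_scene_support(self, clean_scene, clean_result):
        """Corruption-free: corrected marker images are bright exactly where
        the noiseless scene is."""
        _, _, truth = clean_scene
        corrected = clean_result["corrected"]
        for name in ("CD45", "DAPI"):
            scene = truth.scenes[name]
            img = corrected[name]
            on = scene > 0
            assert img[on].mean() > 50 * max(img[~on].mean(), 1e-9)
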