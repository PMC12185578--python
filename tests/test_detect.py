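import numpy as np
import pytest
from scipy import ndimage

from dabdepth import (
    BlobSpec, CalibratedImage, DetectionParams, SkinPhantomConfig, StainBasis,
    detect_dab_areas, generate_phantom, resample_to_detection_grid,
    subtract_background,
)
from dabdepth.stains import od_to_rgb


class TestParams:
    def test_table_defaults(self):
        p = DetectionParams()
        assert (p.pixel_size_um, p.background_radius_um, p.median_radius_um) == (0.6892, 20.0, 0.0)
        assert (p.gaussian_sigma_um, p.min_area_um2, p.max_area_um2) == (2.0, 5.0, 40_000.0)
        assert (p.threshold_od, p.max_background_od) == (0.20, 2.0)
        assert not p.split_by_shape and p.smooth_boundaries

    @pytest.mark.parametrize("bad", [
        {"min_area_um2": 50, "max_area_um2": 5},
        {"threshold_od": 0},
        {"gaussian_sigma_um": -1},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            DetectionParams(**bad)

    def test_dict_round_trip(self):
        p = DetectionParams(threshold_od=0.3)
        assert DetectionParams.from_dict(p.to_dict()) == p


class TestResample:
    def test_identity_at_target(self):
        img = CalibratedImage(np.zeros((10, 10, 3), dtype=np.uint8), 0.6892)
        assert resample_to_detection_grid(img, 0.6892) is img

    def test_double_resolution_upsamples(self):
        img = CalibratedImage(np.zeros((50, 40, 3), dtype=np.uint8), 1.3784)
        out = resample_to_detection_grid(img, 0.6892)
        assert abs(out.height - 100) <= 1 and abs(out.width - 80) <= 1
        assert out.pixel_size_um == 0.6892

    def test_constant_image_stays_constant(self):
        img = CalibratedImage(np.full((30, 30, 3), 77, dtype=np.uint8), 1.0)
        out = resample_to_detection_grid(img, 0.6892)
        assert (out.pixels == 77).all()


class TestSubtractBackground:
    def test_constant_image_fully_removed(self):
        od = np.full((40, 40), 0.7)
        corrected, background, excl = subtract_background(od, 1.0, 10.0, 2.0)
        np.testing.assert_allclose(background, 0.7)
        np.testing.assert_allclose(corrected, 0.0)
        assert not excl.any()

    def test_small_bright_disk_survives_opening(self):
        od = np.zeros((80, 80))
        yy, xx = np.mgrid[:80, :80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 5**2  # radius 5 µm at 1 µm/px
        od[disk] = 1.0
        corrected, background, _ = subtract_background(od, 1.0, 20.0, 2.0)
        np.testing.assert_allclose(background, 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected, od)

    def test_high_background_everywhere_excluded(self):
        od = np.full((30, 30), 2.5)
        _, _, excl = subtract_background(od, 1.0, 5.0, 2.0)
        assert excl.all()

    def test_radius_zero_disables_correction(self):
        od = np.random.default_rng(0).uniform(0, 1, (20, 20))
        corrected, background, _ = subtract_background(od, 1.0, 0.0, 2.0)
        np.testing.assert_allclose(background, 0.0)
        np.testing.assert_allclose(corrected, od)


def blank_region(side_px=200, um=0.6892):
    return CalibratedImage(np.full((side_px, side_px, 3), 255, dtype=np.uint8), um)


class TestDetect:
    def test_blank_white_region_yields_no_blobs(self):
        assert detect_dab_areas(blank_region()) == []

    def test_single_disk_matches_dilation_oracle(self):
        cfg = SkinPhantomConfig(
            width_um=300, height_um=300, noise_sd=0.0,
            blobs=BlobSpec(count=1, radius_um_range=(10.0, 10.0),
                           depth_distribution=("point", 0.5)),
            seed=5,
        )
        img, truth = generate_phantom(cfg)
        blobs = detect_dab_areas(img)
        assert len(blobs) == 1
        planted_px = truth.blobs[0].pixels.shape[0]
        # oracle: blurred planted disk thresholded at params.threshold_od
        p = DetectionParams()
        peak_od_sum = cfg.blobs.peak_od * StainBasis().dab_vector.sum()
        grid = np.zeros(img.shape)
        r_px = 10.0 / img.pixel_size_um
        cy, cx = truth.blobs[0].center_row, truth.blobs[0].center_col
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        grid[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2] = peak_od_sum
        blurred = ndimage.gaussian_filter(grid, p.gaussian_sigma_um / img.pixel_size_um)
        oracle_px = int((blurred > p.threshold_od).sum())
        detected_px = blobs[0].pixels.shape[0]
        # the low threshold dilates the hard-edged disk; area must track the
        # oracle, and always exceed the planted pixel count
        assert detected_px > planted_px
        assert detected_px == pytest.approx(oracle_px, rel=0.10)
        assert blobs[0].area_um2 == pytest.approx(detected_px * img.pixel_size_um**2)

    def test_tiny_speck_below_min_area_dropped(self):
        # 2 µm² speck (radius ~0.8 µm): below Minimum area, must not appear
        cfg = SkinPhantomConfig(
            width_um=200, height_um=300, noise_sd=0.0,
            blobs=BlobSpec(count=1, radius_um_range=(0.8, 0.8),
                           depth_distribution=("point", 0.5)),
            seed=2,
        )
        img, _ = generate_phantom(cfg)
        assert detect_dab_areas(img) == []

    def test_touching_disks_merge_without_shape_splitting(self):
        # two radius-5 µm disks with a 3 µm gap bridge after the 2 µm blur
        um = 0.6892
        n = 200
        od = np.zeros((n, n))
        yy, xx = np.mgrid[:n, :n] * um
        for cx in (60.0, 73.0):  # centers 13 µm apart -> 3 µm boundary gap
            od[(yy - 60) ** 2 + (xx - cx) ** 2 <= 25.0] = 1.6
        pixels = od_to_rgb(od[..., None] * StainBasis().dab_vector)
        img = CalibratedImage(pixels, um)
        blobs = detect_dab_areas(img)
        assert len(blobs) == 1

    def test_raising_threshold_never_adds_pixels(self, small_phantom):
        _, img, _ = small_phantom
        totals = []
        for thr in (0.15, 0.3, 0.6, 1.0):
            blobs = detect_dab_areas(img, DetectionParams(threshold_od=thr))
            totals.append(sum(b.pixels.shape[0] for b in blobs))
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_rotation_invariant_count_and_areas(self, small_phantom):
        _, img, _ = small_phantom
        blobs = detect_dab_areas(img)
        rot = CalibratedImage(np.rot90(img.pixels).copy(), img.pixel_size_um)
        blobs_rot = detect_dab_areas(rot)
        assert len(blobs) == len(blobs_rot)
        areas = sorted(b.area_um2 for b in blobs)
        areas_rot = sorted(b.area_um2 for b in blobs_rot)
        np.testing.assert_allclose(areas, areas_rot, rtol=0.05)

    def test_area_bounds_respected(self, small_phantom):
        _, img, _ = small_phantom
        p = DetectionParams()
        for b in detect_dab_areas(img, p):
            assert p.min_area_um2 <= b.area_um2 <= p.max_area_um2

    def test_blob_order_and_ids_deterministic(self, small_phantom):
        _, img, _ = small_phantom
        blobs1 = detect_dab_areas(img)
        blobs2 = detect_dab_areas(img)
        assert [b.id for b in blobs1] == list(range(len(blobs1)))
        for b1, b2 in zip(blobs1, blobs2):
            np.testing.assert_array_equal(b1.pixels, b2.pixels)
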