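import numpy as np
import pytest
from shapely.geometry import box

from dabdepth import (
    BlobSpec, CalibratedImage, SkinPhantomConfig, TrainingScribbles,
    apply_refinement, classify_pixels, extract_features, generate_phantom,
    train_pixel_classifier,
)
from dabdepth.phantom import scribbles_from_truth
from .conftest import make_flat_mask


@pytest.fixture(scope="module")
def noisy_band_phantom():
    cfg = SkinPhantomConfig(
        width_um=200.0, height_um=250.0, noise_sd=8.0,
        blobs=BlobSpec(count=0), seed=21,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="module")
def trained(noisy_band_phantom):
    img, truth = noisy_band_phantom
    scr = scribbles_from_truth(truth, fraction=0.05, seed=1)
    features = extract_features(img)
    model = train_pixel_classifier(features, scr, seed=7)
    return img, truth, scr, features, model


class TestFeatures:
    def test_seven_features_per_scale(self):
        img = CalibratedImage(np.zeros((20, 20, 3), dtype=np.uint8), 1.0)
        assert extract_features(img, (2.0,)).shape == (20, 20, 7)
        assert extract_features(img, (1.0, 2.0, 4.0)).shape == (20, 20, 21)

    def test_constant_image_constant_features(self):
        img = CalibratedImage(np.full((15, 15, 3), 120, dtype=np.uint8), 1.0)
        f = extract_features(img, (1.0, 3.0))
        assert np.ptp(f.reshape(-1, f.shape[2]), axis=0).max() == pytest.approx(0.0)

    def test_larger_scale_flattens_step_edge(self):
        pix = np.zeros((30, 30, 3), dtype=np.uint8)
        pix[:, 15:] = 200
        img = CalibratedImage(pix, 1.0)
        f = extract_features(img, (1.0, 5.0))
        grad_small = np.abs(np.diff(f[15, :, 0]))
        grad_large = np.abs(np.diff(f[15, :, 7]))
        assert grad_large.max() < grad_small.max()

    def test_nonpositive_scale_rejected(self):
        img = CalibratedImage(np.zeros((5, 5, 3), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError):
            extract_features(img, (0.0,))


class TestTraining:
    def test_heldout_accuracy_on_noisy_bands(self, trained):
        img, truth, scr, features, model = trained
        mask = classify_pixels(model, img, features=features)
        tissue = truth.label_mask.labels > 0
        agree = (mask.labels == truth.label_mask.labels)[tissue].mean()
        assert agree >= 0.95

    def test_missing_class_named_in_error(self, noisy_band_phantom):
        img, truth = noisy_band_phantom
        rows, cols = np.nonzero(truth.label_mask.labels == 2)
        scr = TrainingScribbles(rows[:50], cols[:50], np.full(50, 2, dtype=np.uint8))
        features = extract_features(img)
        with pytest.raises(ValueError, match="squamous.*dermis|dermis.*squamous"):
            train_pixel_classifier(features, scr)

    def test_same_seed_identical_predictions(self, noisy_band_phantom):
        img, truth = noisy_band_phantom
        scr = scribbles_from_truth(truth, fraction=0.02, seed=2)
        features = extract_features(img)
        m1 = train_pixel_classifier(features, scr, seed=3)
        m2 = train_pixel_classifier(features, scr, seed=3)
        p1 = classify_pixels(m1, img, features=features)
        p2 = classify_pixels(m2, img, features=features)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_model_round_trip(self, trained, tmp_path):
        img, _, _, features, model = trained
        model.save(tmp_path / "model.pkl")
        from dabdepth import PixelClassifierModel
        loaded = PixelClassifierModel.load(tmp_path / "model.pkl")
        p1 = classify_pixels(model, img, features=features)
        p2 = classify_pixels(loaded, img, features=features)
        np.testing.assert_array_equal(p1.labels, p2.labels)


class TestClassify:
    def test_pure_white_image_all_outside(self, trained):
        _, _, _, _, model = trained
        white = CalibratedImage(np.full((40, 40, 3), 255, dtype=np.uint8), 0.6892)
        mask = classify_pixels(model, white)
        assert (mask.labels == 0).all()

    def test_output_shape_and_label_range(self, trained):
        img, _, _, features, model = trained
        mask = classify_pixels(model, img, features=features)
        assert mask.shape == img.shape
        assert set(np.unique(mask.labels)) <= {0, 1, 2, 3}

    def test_feature_recipe_mismatch_rejected(self, trained):
        img, _, _, _, model = trained
        bad = extract_features(img, (2.0,))
        with pytest.raises(ValueError, match="recipe"):
            classify_pixels(model, img, features=bad)

    def test_smoothing_zero_is_raw_argmax(self, trained):
        img, _, _, features, model = trained
        raw = classify_pixels(model, img, features=features, smoothing_radius_px=0)
        h, w = img.shape
        pred = model.forest.predict(features.reshape(-1, features.shape[2])).reshape(h, w)
        from dabdepth.stains import rgb_to_od
        pred[rgb_to_od(img).od_sum < 0.05] = 0
        np.testing.assert_array_equal(raw.labels, pred.astype(np.uint8))


class TestRefinement:
    def test_empty_edits_identity(self, flat_mask):
        out = apply_refinement(flat_mask, [])
        np.testing.assert_array_equal(out.labels, flat_mask.labels)
        assert out.labels is not flat_mask.labels

    def test_polygon_relabels_exactly_enclosed_pixels(self):
        mask = make_flat_mask()
        poly = box(4.5, 39.5, 10.5, 44.5)  # pixel centers rows 40-44, cols 5-10
        out = apply_refinement(mask, [(poly, 2)])
        changed = out.labels != mask.labels
        expected = np.zeros_like(changed)
        expected[40:45, 5:11] = True
        np.testing.assert_array_equal(changed, expected)
        assert (out.labels[40:45, 5:11] == 2).all()

    def test_overlapping_edits_last_wins(self, flat_mask):
        p1 = box(1.5, 1.5, 6.5, 6.5)
        p2 = box(3.5, 3.5, 5.5, 5.5)
        out = apply_refinement(flat_mask, [(p1, 3), (p2, 1)])
        assert out.labels[4, 4] == 1
        assert out.labels[2, 2] == 3

    def test_invalid_label_rejected(self, flat_mask):
        with pytest.raises(ValueError):
            apply_refinement(flat_mask, [(box(0, 0, 2, 2), 9)])
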