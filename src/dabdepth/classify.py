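"""Supervised per-pixel tissue classification.

A tree-ensemble classifier labels each pixel as squamous, epidermis or
dermis from multiscale color features (per-channel intensity, per-channel
OD and OD sum, each Gaussian-smoothed at one or more scales).  The
"outside" class is never trained: near-white pixels (OD sum below a
whiteness threshold) are forced to 0 after prediction, matching how blank
slide regions behave in brightfield sections.

The classifier is deliberately per-dataset: staining batches vary, so a
model trained on one protocol is not a universal skin-layer detector and
no pretrained weights ship with the package.  Boundary corrections that a
human operator would brush in interactively are supported as GeoJSON
polygon overrides (:func:`apply_refinement`).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .io import (
    CalibratedImage,
    LabelMask,
    LABEL_NAMES,
    rasterize_polygons,
)
from .stains import rgb_to_od

DEFAULT_SCALES_UM = (1.0, 2.0, 4.0)
TISSUE_CLASSES = (1, 2, 3)

FORMAT_VERSION = 1


@dataclass
class TrainingScribbles:
    """Sparse operator annotations: (row, col) indices with tissue labels."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # values in {1, 2, 3}

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if not (self.rows.shape == self.cols.shape == self.labels.shape):
            raise ValueError("rows, cols, labels must have identical shapes")
        if not np.isin(self.labels, TISSUE_CLASSES).all():
            raise ValueError("scribble labels must be in {1, 2, 3}")

    @classmethod
    def from_mask(cls, labels: np.ndarray) -> "TrainingScribbles":
        """Build scribbles from an indexed image; zeros are unannotated."""
        rows, cols = np.nonzero(labels)
        return cls(rows, cols, labels[rows, cols])

    def missing_classes(self) -> list[str]:
        present = set(np.unique(self.labels).tolist())
        return [LABEL_NAMES[c] for c in TISSUE_CLASSES if c not in present]


def extract_features(
    img: CalibratedImage, scales_um: tuple[float, ...] = DEFAULT_SCALES_UM
) -> np.ndarray:
    """Per-pixel feature stack, shape H×W×(7·n_scales).

    Channels per scale, in fixed order: R, G, B intensities, per-channel
    OD, OD sum — each Gaussian-smoothed at that scale (in µm).
    """
    if len(scales_um) < 1:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales_um):
        raise ValueError("scales must be positive")
    od_img = rgb_to_od(img)
    base = np.concatenate(
        [
            img.pixels.astype(np.float64),
            od_img.od,
            od_img.od_sum[..., None],
        ],
        axis=2,
    )
    stacks = []
    for scale in scales_um:
        sigma_px = scale / img.pixel_size_um
        smoothed = ndimage.gaussian_filter(base, sigma=(sigma_px, sigma_px, 0))
        stacks.append(smoothed)
    return np.concatenate(stacks, axis=2)


@dataclass
class PixelClassifierModel:
    """A fitted tissue classifier together with its feature recipe."""

    forest: RandomForestClassifier
    scales_um: tuple[float, ...]
    training_accuracy: float
    seed: int
    version: int = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls) or model.version != FORMAT_VERSION:
            raise ValueError("incompatible classifier file")
        return model


def train_pixel_classifier(
    features: np.ndarray,
    scribbles: TrainingScribbles,
    seed: int = 0,
    scales_um: tuple[float, ...] = DEFAULT_SCALES_UM,
    n_trees: int = 50,
    max_depth: int | None = 12,
) -> PixelClassifierModel:
    """Fit the tree ensemble on scribbled pixels.

    All three tissue classes must be represented; a missing class is an
    error naming it (training a two-class model would silently mislabel
    the third tissue everywhere).
    """
    missing = scribbles.missing_classes()
    if missing:
        raise ValueError(f"missing training class(es): {', '.join(missing)}")
    x = features[scribbles.rows, scribbles.cols]
    y = scribbles.labels
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    acc = float((forest.predict(x) == y).mean())
    return PixelClassifierModel(
        forest=forest, scales_um=tuple(scales_um), training_accuracy=acc, seed=seed
    )


def classify_pixels(
    model: PixelClassifierModel,
    img: CalibratedImage,
    features: np.ndarray | None = None,
    smoothing_radius_px: int = 2,
    whiteness_threshold_od: float = 0.05,
) -> LabelMask:
    """Predict a tissue label per pixel.

    Argmax prediction, then majority smoothing in a disk of
    ``smoothing_radius_px`` (0 disables it), then near-white pixels
    (OD sum < ``whiteness_threshold_od``) forced to outside.
    """
    if features is None:
        features = extract_features(img, model.scales_um)
    expected = 7 * len(model.scales_um)
    if features.shape[2] != expected:
        raise ValueError(
            f"feature recipe mismatch: got {features.shape[2]} features, "
            f"model expects {expected}"
        )
    h, w = features.shape[:2]
    pred = model.forest.predict(features.reshape(-1, features.shape[2]))
    pred = pred.reshape(h, w).astype(np.uint8)
    if smoothing_radius_px > 0:
        pred = _majority_smooth(pred, smoothing_radius_px)
    od_sum = rgb_to_od(img).od_sum
    pred[od_sum < whiteness_threshold_od] = 0
    return LabelMask(pred, img.pixel_size_um)


def _majority_smooth(pred: np.ndarray, radius: int) -> np.ndarray:
    """Majority vote in a disk footprint; ties favor the lowest class id."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (yy * yy + xx * xx) <= radius * radius
    votes = [
        ndimage.convolve((pred == c).astype(np.float64), footprint.astype(np.float64),
                         mode="nearest")
        for c in TISSUE_CLASSES
    ]
    winner = np.argmax(np.stack(votes, axis=0), axis=0)
    return np.asarray(TISSUE_CLASSES, dtype=np.uint8)[winner]


def apply_refinement(mask: LabelMask, edits) -> LabelMask:
    """Overwrite pixels inside each edit polygon with its target label.

    ``edits`` is a list of ``(shapely geometry in µm, label)`` pairs
    applied in order — the last listed polygon wins on overlap, mirroring
    how an operator's final brush stroke overrides earlier ones.
    """
    if not edits:
        return LabelMask(mask.labels.copy(), mask.pixel_size_um)
    for geom, lab in edits:
        if not geom.is_valid:
            raise ValueError("invalid refinement polygon")
        if lab not in (0, 1, 2, 3):
            raise ValueError(f"refinement label {lab} outside {{0..3}}")
    overlay = rasterize_polygons(
        [(g, lab + 1) for g, lab in edits], mask.shape, mask.pixel_size_um
    )
    out = mask.labels.copy()
    touched = overlay > 0
    out[touched] = overlay[touched] - 1
    return LabelMask(out, mask.pixel_size_um)
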