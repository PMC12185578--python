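"""Calibrated raster I/O, label masks, square regions and tabular outputs.

Conventions used throughout the package: image origin at the top-left,
``x`` = column, ``y`` = row, pixel centers at integer coordinates, 0-based
half-open crops.  Physical coordinates (µm) refer to the image frame, not
to any geographic system; GeoJSON files produced or consumed here store
polygon vertices in µm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio
import shapely
from shapely.geometry import shape as geojson_shape

logger = logging.getLogger(__name__)

#: tissue label codes shared by every module
LABEL_OUTSIDE = 0
LABEL_SQUAMOUS = 1
LABEL_EPIDERMIS = 2
LABEL_DERMIS = 3

LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_SQUAMOUS: "squamous",
    LABEL_EPIDERMIS: "epidermis",
    LABEL_DERMIS: "dermis",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class CalibratedImage:
    """RGB brightfield image with isotropic pixel calibration.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        Intensities in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel in µm; must be positive.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected 3 channels (H, W, 3), got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMask:
    """Per-pixel tissue classification with calibration.

    ``labels`` holds {0: outside, 1: squamous, 2: epidermis, 3: dermis}.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        bad = ~np.isin(self.labels, (0, 1, 2, 3))
        if bad.any():
            values = sorted(np.unique(self.labels[bad]).tolist())
            raise ValueError(f"labels outside {{0,1,2,3}}: {values}")
        self.labels = self.labels.astype(np.uint8)
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class SquareRegion:
    """Axis-aligned square analysis region in µm (image frame).

    ``origin_x_um``/``origin_y_um`` locate the top-left corner; the crop is
    half-open in pixel space.
    """

    origin_x_um: float
    origin_y_um: float
    side_um: float

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise ValueError("side_um must be positive")

    def to_pixel_slices(self, pixel_size_um: float, shape: tuple[int, int]):
        """Convert to (row_slice, col_slice); raises if outside the image."""
        row0 = _round_half_up(self.origin_y_um / pixel_size_um)
        col0 = _round_half_up(self.origin_x_um / pixel_size_um)
        side_px = _round_half_up(self.side_um / pixel_size_um)
        if side_px < 1:
            raise ValueError("region smaller than one pixel")
        if row0 < 0 or col0 < 0 or row0 + side_px > shape[0] or col0 + side_px > shape[1]:
            raise ValueError(
                f"region [{row0}:{row0 + side_px}, {col0}:{col0 + side_px}] "
                f"exceeds image bounds {shape}"
            )
        return slice(row0, row0 + side_px), slice(col0, col0 + side_px)


def _round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (deterministic µm→px rule)."""
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# raster I/O

def read_image(path: str | Path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read a TIFF or PNG as a :class:`CalibratedImage`.

    Calibration resolution order: TIFF resolution tags, then the
    ``pixel_size_um`` argument (typically from a config file).  A fallback
    to the config value is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tag_um = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            tag_um = _pixel_size_from_tags(page)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected 3 channels, got shape {arr.shape} in {path}")
    if tag_um is not None:
        um = tag_um
    elif pixel_size_um is not None:
        logger.info("no calibration tags in %s; using config value %g µm/px", path, pixel_size_um)
        um = pixel_size_um
    else:
        raise ValueError(f"{path}: no calibration in file and no config value given")
    if um <= 0:
        raise ValueError(f"non-positive pixel calibration {um}")
    return CalibratedImage(arr, um)


def _pixel_size_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimeter
        return 10_000.0 / px_per_unit
    if unit == 2:  # inch
        return 25_400.0 / px_per_unit
    return None


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image; TIFF carries resolution tags (px/cm)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_per_cm = 10_000.0 / img.pixel_size_um
        tifffile.imwrite(
            path, img.pixels, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER"
        )
    else:
        iio.imwrite(path, img.pixels)


def write_float_map(arr: np.ndarray, path: str | Path, pixel_size_um: float) -> None:
    """Write a float field (depth map, OD map) as 32-bit TIFF."""
    px_per_cm = 10_000.0 / pixel_size_um
    tifffile.imwrite(
        Path(path), np.asarray(arr, dtype=np.float32),
        resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER",
    )


def crop_region(img: CalibratedImage, region: SquareRegion) -> CalibratedImage:
    """Extract a square region; calibration is preserved.

    The pixel side length is ``round_half_up(side_um / pixel_size_um)``.
    """
    rows, cols = region.to_pixel_slices(img.pixel_size_um, img.shape)
    return CalibratedImage(img.pixels[rows, cols].copy(), img.pixel_size_um)


def crop_mask(mask: LabelMask, region: SquareRegion) -> LabelMask:
    rows, cols = region.to_pixel_slices(mask.pixel_size_um, mask.shape)
    return LabelMask(mask.labels[rows, cols].copy(), mask.pixel_size_um)


# ---------------------------------------------------------------------------
# label masks

def read_label_mask(
    path: str | Path,
    pixel_size_um: float,
    shape: tuple[int, int] | None = None,
) -> LabelMask:
    """Read a label mask from an indexed PNG/TIFF or a GeoJSON file.

    Raster masks must use values {0 outside, 1 squamous, 2 epidermis,
    3 dermis}.  GeoJSON FeatureCollections are rasterized on the image grid
    given by ``shape`` (required then); each feature needs
    ``properties.classification`` ∈ {squamous, epidermis, dermis} and
    polygon coordinates in µm.
    """
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        if shape is None:
            raise ValueError("rasterizing GeoJSON requires the target image shape")
        features = _load_feature_collection(path)
        labels = np.zeros(shape, dtype=np.uint8)
        for poly, lab in features:
            _paint_polygon(labels, poly, lab, pixel_size_um)
        return LabelMask(labels, pixel_size_um)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: label mask must be a single-channel indexed image")
    return LabelMask(arr, pixel_size_um)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.labels)


def _load_feature_collection(path: Path) -> list[tuple[shapely.Geometry, int]]:
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [doc] if doc.get("type") == "Feature" else [])
    out = []
    for feat in feats:
        cls = feat.get("properties", {}).get("classification")
        if isinstance(cls, dict):  # QuPath-style {"name": ...}
            cls = cls.get("name")
        if cls is None:
            raise ValueError("feature missing properties.classification")
        cls = str(cls).lower()
        if cls not in NAME_TO_LABEL or cls == "outside":
            raise ValueError(f"unknown classification {cls!r}")
        geom = geojson_shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for classification {cls!r} (self-intersection?)")
        out.append((geom, NAME_TO_LABEL[cls]))
    return out


def _paint_polygon(labels: np.ndarray, geom, value: int, pixel_size_um: float) -> None:
    """Set label ``value`` on pixels whose centers fall inside ``geom`` (µm)."""
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor(minx / pixel_size_um)) - 1, 0)
    c1 = min(int(np.ceil(maxx / pixel_size_um)) + 2, labels.shape[1])
    r0 = max(int(np.floor(miny / pixel_size_um)) - 1, 0)
    r1 = min(int(np.ceil(maxy / pixel_size_um)) + 2, labels.shape[0])
    if c1 <= c0 or r1 <= r0:
        return
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(
        geom, cols.ravel() * pixel_size_um, rows.ravel() * pixel_size_um
    ).reshape(rows.shape)
    sub = labels[r0:r1, c0:c1]
    sub[inside] = value


def rasterize_polygons(
    features: list[tuple[shapely.Geometry, int]],
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Rasterize (geometry, label) pairs in list order; later entries win."""
    labels = np.zeros(shape, dtype=np.uint8)
    for geom, lab in features:
        _paint_polygon(labels, geom, lab, pixel_size_um)
    return labels


# ---------------------------------------------------------------------------
# bundled outputs

def write_outputs(
    out_dir: str | Path,
    tables: dict[str, "object"] | None = None,
    masks: dict[str, LabelMask] | None = None,
    float_maps: dict[str, tuple[np.ndarray, float]] | None = None,
    figures: dict[str, "object"] | None = None,
) -> list[Path]:
    """Write CSV tables, label masks, 32-bit float maps and figures.

    Returns the list of files written.  ``tables`` values are pandas
    DataFrames, ``float_maps`` values are ``(array, pixel_size_um)`` pairs,
    ``figures`` values are matplotlib Figures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for name, mask in (masks or {}).items():
        p = out_dir / f"{name}.png"
        write_label_mask(mask, p)
        written.append(p)
    for name, (arr, um) in (float_maps or {}).items():
        p = out_dir / f"{name}.tif"
        write_float_map(arr, p, um)
        written.append(p)
    for name, fig in (figures or {}).items():
        p = out_dir / f"{name}.png"
        fig.savefig(p, dpi=150)
        written.append(p)
    return written
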