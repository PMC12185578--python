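"""DAB-positive area ("blob") detection.

The chain mirrors a brightfield cell-detection recipe: resample to the
calibrated working pixel size, build the OD-sum channel, optional median
filter, Gaussian blur, local background subtraction by grayscale opening,
fixed OD threshold, 8-connected components, and an area filter.  Shape
based splitting is disabled (touching areas stay merged) because the
irregular dendritic morphology of Langerhans cells makes per-cell counts
meaningless in 2-D sections; areas are the objects.

Defaults on :class:`DetectionParams` are the optimized operating point
used for CD1a/DAB on fast-red counterstained skin sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import morphology, transform, filters
from skimage.measure import find_contours
from shapely import affinity
from shapely.geometry import Polygon

from .io import CalibratedImage, SquareRegion, crop_region
from .stains import rgb_to_od

_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class DetectionParams:
    """Parameter block for the blob detector (lengths in µm, areas µm²)."""

    pixel_size_um: float = 0.6892
    background_radius_um: float = 20.0
    median_radius_um: float = 0.0
    gaussian_sigma_um: float = 2.0
    min_area_um2: float = 5.0
    max_area_um2: float = 40_000.0
    threshold_od: float = 0.20
    max_background_od: float = 2.0
    split_by_shape: bool = False
    smooth_boundaries: bool = True

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "background_radius_um", "median_radius_um",
                     "gaussian_sigma_um", "min_area_um2", "max_area_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um == 0:
            raise ValueError("pixel_size_um must be positive")
        if self.min_area_um2 > self.max_area_um2:
            raise ValueError("min_area_um2 exceeds max_area_um2")
        if self.threshold_od <= 0:
            raise ValueError("threshold_od must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class DabBlob:
    """One connected DAB-positive area with its depth measurements."""

    id: int
    pixels: np.ndarray            # N×2 (row, col) on the detection grid
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    mean_od_sum: float
    boundary_polygon: Polygon | None = None
    d_rel_values: np.ndarray | None = None
    mean_d_rel: float | None = None
    mean_dist_from_epi_um: float | None = None
    mean_dist_from_derm_um: float | None = None


def resample_to_detection_grid(img: CalibratedImage, target_um: float) -> CalibratedImage:
    """Bilinear resample to the target pixel size (identity within 1e-4)."""
    if target_um <= 0:
        raise ValueError("target pixel size must be positive")
    scale = img.pixel_size_um / target_um
    if abs(scale - 1.0) < 1e-4:
        return img
    new_shape = (
        max(int(round(img.height * scale)), 1),
        max(int(round(img.width * scale)), 1),
    )
    out = transform.resize(
        img.pixels.astype(np.float64), new_shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return CalibratedImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), target_um)


def subtract_background(
    od_sum: np.ndarray, pixel_size_um: float, radius_um: float, max_background_od: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local background via grayscale opening with a disk element.

    Returns ``(corrected, background, exclusion_mask)``; the exclusion
    mask is true where the estimated background itself exceeds
    ``max_background_od`` (stain pooling, folds).  Radius 0 disables the
    correction (background identically 0).
    """
    if radius_um < 0:
        raise ValueError("radius must be >= 0")
    if radius_um == 0:
        background = np.zeros_like(od_sum)
    else:
        r_px = max(int(round(radius_um / pixel_size_um)), 1)
        background = morphology.opening(od_sum, morphology.disk(r_px))
    corrected = np.maximum(od_sum - background, 0.0)
    exclusion = background > max_background_od
    return corrected, background, exclusion


def _component_polygon(component: np.ndarray, simplify_tol: float) -> Polygon | None:
    """Outer boundary polygon of a padded binary component, in pixel units."""
    padded = np.pad(component.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # find_contours yields (row, col); shift for padding, swap to (x, y)
    xy = np.stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0], axis=1)
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if simplify_tol > 0:
        poly = poly.simplify(simplify_tol, preserve_topology=True)
    return poly


def detect_dab_areas(
    img: CalibratedImage,
    params: DetectionParams | None = None,
    region: SquareRegion | None = None,
) -> list[DabBlob]:
    """Run the full detection chain on an image or a square region of it.

    Pipeline: crop → resample → OD sum → median (if radius > 0) →
    Gaussian blur → background subtraction → threshold → drop excluded
    pixels → 8-connected components → area filter → optional boundary
    smoothing.  Blobs are ordered by the (row, col) of their
    topmost-leftmost pixel, which also defines their ids.
    """
    params = params or DetectionParams()
    if region is not None:
        img = crop_region(img, region)
    img = resample_to_detection_grid(img, params.pixel_size_um)
    um = img.pixel_size_um
    od_sum = rgb_to_od(img).od_sum

    if params.median_radius_um > 0:
        r_px = max(int(round(params.median_radius_um / um)), 1)
        od_sum = filters.median(od_sum, morphology.disk(r_px))
    if params.gaussian_sigma_um > 0:
        od_sum = ndimage.gaussian_filter(od_sum, sigma=params.gaussian_sigma_um / um)

    corrected, _, exclusion = subtract_background(
        od_sum, um, params.background_radius_um, params.max_background_od
    )
    binary = corrected > params.threshold_od
    binary &= ~exclusion

    comp_labels, n = ndimage.label(binary, structure=_STRUCT_8)
    if n == 0:
        return []

    px_area = um * um
    blobs: list[DabBlob] = []
    objects = ndimage.find_objects(comp_labels)
    for idx, slc in enumerate(objects, start=1):
        component = comp_labels[slc] == idx
        if params.smooth_boundaries:
            # pad so closing is not clipped at the bounding-box border
            padded = np.pad(component, 2)
            padded = morphology.closing(padded, morphology.disk(1))
            rows, cols = np.nonzero(padded)
            rows = rows - 2 + slc[0].start
            cols = cols - 2 + slc[1].start
            keep = (
                (rows >= 0) & (rows < binary.shape[0])
                & (cols >= 0) & (cols < binary.shape[1])
            )
            rows, cols = rows[keep], cols[keep]
            keep = ~exclusion[rows, cols]
            rows, cols = rows[keep], cols[keep]
        else:
            rows, cols = np.nonzero(component)
            rows = rows + slc[0].start
            cols = cols + slc[1].start
        area = rows.size * px_area
        if not (params.min_area_um2 <= area <= params.max_area_um2):
            continue
        poly = None
        if params.smooth_boundaries:
            poly = _component_polygon(comp_labels[slc] == idx, simplify_tol=0.5)
            if poly is not None:
                poly = affinity.translate(poly, xoff=slc[1].start, yoff=slc[0].start)
        blobs.append(
            DabBlob(
                id=-1,
                pixels=np.stack([rows, cols], axis=1),
                area_um2=float(area),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_od_sum=float(corrected[rows, cols].mean()),
                boundary_polygon=poly,
            )
        )
    # deterministic order: topmost, then leftmost pixel
    def _key(b: DabBlob):
        i = np.lexsort((b.pixels[:, 1], b.pixels[:, 0]))[0]
        return (int(b.pixels[i, 0]), int(b.pixels[i, 1]))

    blobs.sort(key=_key)
    for i, b in enumerate(blobs):
        b.id = i
    return blobs


def attach_depths(blobs: list[DabBlob], field) -> list[DabBlob]:
    """Annotate blobs in place with depth statistics from a
    :class:`~dabdepth.depth.RelativeDepthField` on the same grid."""
    for b in blobs:
        r, c = b.pixels[:, 0], b.pixels[:, 1]
        b.d_rel_values = field.d_rel[r, c]
        b.mean_d_rel = float(b.d_rel_values.mean())
        b.mean_dist_from_epi_um = float(field.d_top_epi_um[r, c].mean())
        b.mean_dist_from_derm_um = float(field.d_top_derm_um[r, c].mean())
    return blobs
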