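"""Euclidean distance maps and the relative epidermal depth field.

Each pixel of the epidermis gets a dimensionless depth

    d_rel = D_top_epi / (D_top_epi + D_top_derm)

where ``D_top_epi`` is the Euclidean distance (between pixel centers) to
the nearest pixel above the epidermis (outside or squamous) and
``D_top_derm`` the distance to the nearest dermis pixel.  The field is 0
on outside/squamous pixels and 1 on dermis pixels; inside the epidermis
it runs from ≈0 at the squamous interface to ≈1 at the basal lamina.
Because distances are measured between pixel centers, both maps are at
least one pixel on epidermis pixels and the denominator never vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LabelMask, LABEL_EPIDERMIS, LABEL_DERMIS
from .topology import TissueMasks


@dataclass
class RelativeDepthField:
    """Absolute distance maps (µm) and the relative depth in [0, 1]."""

    d_top_epi_um: np.ndarray
    d_top_derm_um: np.ndarray
    d_rel: np.ndarray
    pixel_size_um: float


def edm(mask: np.ndarray, pixel_size_um: float = 1.0) -> np.ndarray:
    """Exact Euclidean distance map of a boolean mask, in µm.

    Each true pixel maps to the Euclidean distance from its center to the
    nearest false pixel center, times the calibration; false pixels map
    to 0.  Raises on an all-true mask (no background to measure from).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("all-true mask: no background pixel to measure distance to")
    return ndimage.distance_transform_edt(mask) * pixel_size_um


def relative_depth(masks: TissueMasks, labels: LabelMask) -> RelativeDepthField:
    """Compute the two distance maps and the relative depth field."""
    um = masks.pixel_size_um
    d_epi = edm(masks.inner_mask, um)
    d_derm = edm(masks.outer_mask, um)
    lab = labels.labels
    epidermis = lab == LABEL_EPIDERMIS
    if not epidermis.any():
        raise ValueError("degenerate mask: no epidermis pixels")
    d_rel = np.zeros(lab.shape, dtype=np.float64)
    d_rel[lab == LABEL_DERMIS] = 1.0
    denom = d_epi + d_derm
    d_rel[epidermis] = d_epi[epidermis] / denom[epidermis]
    # dermis-side pixels absorbed by the flood fill but not labeled dermis
    absorbed = masks.inner_mask & ~epidermis & ~masks.outer_mask
    d_rel[absorbed] = 1.0
    return RelativeDepthField(
        d_top_epi_um=d_epi, d_top_derm_um=d_derm, d_rel=d_rel, pixel_size_um=um
    )


def flat_band_depth(row: int, y_top_epi: int, y_bottom_epi: int) -> float:
    """Closed-form d_rel for flat horizontal bands (test oracle).

    For an epidermis occupying rows ``y_top_epi..y_bottom_epi`` inclusive,
    with non-epidermis above and below, pixel-center distances give
    ``d_rel(row) = (row - y_top_epi + 1) / (y_bottom_epi - y_top_epi + 2)``.
    Rows above return 0, rows below return 1.
    """
    if row < y_top_epi:
        return 0.0
    if row > y_bottom_epi:
        return 1.0
    return (row - y_top_epi + 1) / (y_bottom_epi - y_top_epi + 2)
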