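"""Optical-density conversion and two-stain linear unmixing.

Brightfield chromogens follow Beer–Lambert: per-channel optical density
``OD_c = -log10(I_c / I0)`` is linear in stain amount, so a pixel's OD
3-vector decomposes onto the DAB and counterstain unit vectors by least
squares.  The blob detector operates on the OD *sum* channel; the unmixed
DAB map is exported for quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CalibratedImage

#: saturation floor, in intensity units, applied before the log
OD_EPSILON = 1.0

#: standard DAB absorbance vector (per-channel OD fractions, unit norm)
DEFAULT_DAB_VECTOR = (0.268, 0.570, 0.776)
#: red nuclear counterstain: absorbs mostly green, some blue
DEFAULT_COUNTERSTAIN_VECTOR = (0.21, 0.85, 0.48)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass
class StainBasis:
    """A pair of stain absorbance directions and the white reference.

    Vectors are normalized on construction; they must be non-negative and
    linearly independent.
    """

    dab_vector: np.ndarray = DEFAULT_DAB_VECTOR
    counterstain_vector: np.ndarray = DEFAULT_COUNTERSTAIN_VECTOR
    i0: float = 255.0

    def __post_init__(self) -> None:
        self.dab_vector = _unit(self.dab_vector)
        self.counterstain_vector = _unit(self.counterstain_vector)
        if (self.dab_vector < 0).any() or (self.counterstain_vector < 0).any():
            raise ValueError("stain vectors must be non-negative")
        cross = np.linalg.norm(np.cross(self.dab_vector, self.counterstain_vector))
        if cross < 1e-8:
            raise ValueError("stain vectors are collinear")
        if self.i0 <= 0:
            raise ValueError("white reference i0 must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """3×2 mixing matrix with stains as columns (DAB first)."""
        return np.stack([self.dab_vector, self.counterstain_vector], axis=1)


@dataclass
class ODImage:
    """Per-channel optical densities plus their per-pixel sum."""

    od: np.ndarray        # H×W×3, >= 0
    od_sum: np.ndarray    # H×W
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.od).all():
            raise ValueError("non-finite OD values")


def rgb_to_od(img: CalibratedImage, i0: float = 255.0) -> ODImage:
    """Convert intensities to optical density (clipped to ≥ 0).

    Zero intensities are floored at ``OD_EPSILON`` so the log stays finite;
    intensities above ``i0`` clip to OD 0.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    intensity = np.maximum(img.pixels.astype(np.float64), OD_EPSILON)
    od = -np.log10(intensity / i0)
    np.clip(od, 0.0, None, out=od)
    return ODImage(od=od, od_sum=od.sum(axis=2), pixel_size_um=img.pixel_size_um)


def unmix(od_img: ODImage, basis: StainBasis | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares projection of each OD vector onto the two stains.

    Returns ``(dab_map, counterstain_map)``; negative coefficients are
    clipped to zero.
    """
    basis = basis or StainBasis()
    m = basis.matrix                       # 3×2
    pinv = np.linalg.pinv(m)               # 2×3
    flat = od_img.od.reshape(-1, 3)
    coeffs = flat @ pinv.T                 # N×2
    np.clip(coeffs, 0.0, None, out=coeffs)
    h, w = od_img.od_sum.shape
    return coeffs[:, 0].reshape(h, w), coeffs[:, 1].reshape(h, w)


def reconstruct(
    dab: np.ndarray, counterstain: np.ndarray, basis: StainBasis | None = None
) -> np.ndarray:
    """Inverse of :func:`unmix` for noise-free coefficient maps (H×W×3 OD)."""
    basis = basis or StainBasis()
    return (
        dab[..., None] * basis.dab_vector
        + counterstain[..., None] * basis.counterstain_vector
    )


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Render an OD image back to uint8 intensities via Beer–Lambert."""
    intensity = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
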