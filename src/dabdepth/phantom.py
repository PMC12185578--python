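"""Synthetic skin-section phantoms with ground truth.

A phantom is a layered cross-section rendered top-to-bottom as
background (blank slide), squamous band (stratum corneum), epidermis and
dermis, each carrying a fast-red-like counterstain at a band-specific
concentration.  DAB-stained blobs stand in for CD1a⁺ Langerhans cells:
disks (optionally dendritic star shapes) planted at controlled relative
depths inside the epidermis.  Rendering goes through optical density —
band OD plus blob OD added linearly, then ``I = i0 · 10^(−OD)`` — so
stain unmixing is exactly invertible in the noise-free limit.  Gaussian
read noise is added last and clipped to [0, 255].

Interfaces may undulate sinusoidally (rete-ridge caricature); blob
placement then uses the local column geometry.  The flat-band case has a
closed-form depth (:func:`closed_form_depth`) used as the oracle for the
distance pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CalibratedImage, LabelMask, _round_half_up
from .stains import StainBasis, od_to_rgb


@dataclass
class BlobSpec:
    """How many DAB blobs to plant and where on the depth axis.

    ``depth_distribution`` is one of ``("point", d)``, ``("uniform", lo,
    hi)``, ``("beta", alpha, beta)`` or ``("bimodal", d1, d2, weight1,
    sd)`` — the last emulating the double-peaked mid-epidermal pattern
    seen in resting skin rather than a single Gaussian mode.
    """

    count: int = 50
    radius_um_range: tuple[float, float] = (5.0, 8.0)
    peak_od: float = 1.0
    depth_distribution: tuple = ("uniform", 0.1, 0.9)
    min_separation_um: float = 30.0
    shape: str = "disk"  # or "star"


@dataclass
class SkinPhantomConfig:
    """Geometry, optics and noise of a synthetic skin section."""

    width_um: float = 500.0
    height_um: float = 500.0
    pixel_size_um: float = 0.6892
    squamous_thickness_um: float = 20.0
    epidermis_thickness_um: float = 100.0
    outside_thickness_um: float = 50.0
    undulation_amplitude_um: float = 0.0
    undulation_wavelength_um: float = 150.0
    # counterstain concentration per band (dimensionless OD multipliers)
    squamous_counterstain: float = 0.25
    epidermis_counterstain: float = 0.55
    dermis_counterstain: float = 0.35
    noise_sd: float = 5.0
    blobs: BlobSpec = field(default_factory=BlobSpec)
    basis: StainBasis = field(default_factory=StainBasis)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.squamous_thickness_um, self.epidermis_thickness_um) <= 0:
            raise ValueError("band thicknesses must be positive")
        if self.blobs.count > 0:
            r_hi = self.blobs.radius_um_range[1]
            if r_hi >= self.epidermis_thickness_um / 2:
                raise ValueError("blob radius must be below half the epidermis thickness")


@dataclass
class PlantedBlob:
    center_row: int
    center_col: int
    radius_um: float
    planted_d_rel: float
    pixels: np.ndarray  # N×2 (row, col)


@dataclass
class PhantomTruth:
    label_mask: LabelMask
    blobs: list[PlantedBlob]
    #: per-column top epidermis row (first epidermis pixel)
    y_top_epi: np.ndarray
    #: per-column bottom epidermis row (last epidermis pixel)
    y_bottom_epi: np.ndarray


def _band_rows(cfg: SkinPhantomConfig, n_cols: int):
    """Per-column first rows of squamous, epidermis and dermis bands."""
    um = cfg.pixel_size_um
    base_sq = _round_half_up(cfg.outside_thickness_um / um)
    base_epi = base_sq + _round_half_up(cfg.squamous_thickness_um / um)
    base_derm = base_epi + _round_half_up(cfg.epidermis_thickness_um / um)
    cols = np.arange(n_cols)
    if cfg.undulation_amplitude_um > 0:
        wave = cfg.undulation_amplitude_um / um * np.sin(
            2 * np.pi * cols * um / cfg.undulation_wavelength_um
        )
        shift = np.rint(wave).astype(int)
    else:
        shift = np.zeros(n_cols, dtype=int)
    return base_sq + shift, base_epi + shift, base_derm + shift


def closed_form_depth(cfg: SkinPhantomConfig, column: int, row: int) -> float:
    """Analytic d_rel of a pixel in a *flat-band* phantom (test oracle).

    With epidermis rows ``y_top..y_bottom`` inclusive, pixel-center
    distances give ``(row − y_top + 1)/(y_bottom − y_top + 2)``; rows
    above map to 0 and rows below to 1.  Undefined for undulating
    interfaces.
    """
    if cfg.undulation_amplitude_um != 0:
        raise ValueError("closed-form depth requires flat interfaces")
    n_cols = _round_half_up(cfg.width_um / cfg.pixel_size_um)
    _, y_epi, y_derm = _band_rows(cfg, n_cols)
    y_top, y_bottom = int(y_epi[0]), int(y_derm[0]) - 1
    if row < y_top:
        return 0.0
    if row > y_bottom:
        return 1.0
    return (row - y_top + 1) / (y_bottom - y_top + 2)


def _sample_depths(spec: BlobSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.depth_distribution[0]
    n = spec.count
    if kind == "point":
        return np.full(n, float(spec.depth_distribution[1]))
    if kind == "uniform":
        lo, hi = spec.depth_distribution[1:3]
        return rng.uniform(lo, hi, n)
    if kind == "beta":
        a, b = spec.depth_distribution[1:3]
        return rng.beta(a, b, n)
    if kind == "bimodal":
        d1, d2, w1, sd = spec.depth_distribution[1:5]
        pick = rng.random(n) < w1
        vals = np.where(pick, rng.normal(d1, sd, n), rng.normal(d2, sd, n))
        return np.clip(vals, 0.02, 0.98)
    raise ValueError(f"unknown depth distribution {kind!r}")


def _blob_mask(shape, center, radius_px, kind, rng):
    """Boolean pixel mask for one blob."""
    r0, c0 = center
    r_int = int(np.ceil(radius_px)) + 1
    rr, cc = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    if kind == "disk":
        local = (rr * rr + cc * cc) <= radius_px * radius_px
    elif kind == "star":
        theta = np.arctan2(rr, cc)
        wobble = 1.0 + 0.35 * np.sin(5 * theta + rng.uniform(0, 2 * np.pi))
        local = np.hypot(rr, cc) <= radius_px * wobble
    else:
        raise ValueError(f"unknown blob shape {kind!r}")
    rows = rr[local] + r0
    cols = cc[local] + c0
    keep = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[keep], cols[keep]


def generate_phantom(cfg: SkinPhantomConfig) -> tuple[CalibratedImage, PhantomTruth]:
    """Render a phantom and its ground truth; same seed → identical output."""
    rng = np.random.default_rng(cfg.seed)
    um = cfg.pixel_size_um
    n_rows = _round_half_up(cfg.height_um / um)
    n_cols = _round_half_up(cfg.width_um / um)
    y_sq, y_epi, y_derm = _band_rows(cfg, n_cols)

    rows = np.arange(n_rows)[:, None]
    labels = np.zeros((n_rows, n_cols), dtype=np.uint8)
    labels[(rows >= y_sq[None, :]) & (rows < y_epi[None, :])] = 1
    labels[(rows >= y_epi[None, :]) & (rows < y_derm[None, :])] = 2
    labels[rows >= y_derm[None, :]] = 3

    counter = np.zeros((n_rows, n_cols))
    counter[labels == 1] = cfg.squamous_counterstain
    counter[labels == 2] = cfg.epidermis_counterstain
    counter[labels == 3] = cfg.dermis_counterstain

    dab = np.zeros((n_rows, n_cols))
    planted: list[PlantedBlob] = []
    spec = cfg.blobs
    if spec.count > 0:
        depths = _sample_depths(spec, rng)
        radii = rng.uniform(*spec.radius_um_range, spec.count)
        centers: list[tuple[int, int]] = []
        min_sep_px = spec.min_separation_um / um
        for d_target, r_um in zip(depths, radii):
            r_px = r_um / um
            placed = False
            # if the requested separation cannot be honored (crowded depth
            # lines), relax it stepwise down to bare non-overlap
            for sep_px in (min_sep_px, 0.8 * min_sep_px, 0.6 * min_sep_px,
                           2.2 * r_px):
                for _ in range(2000):
                    col = int(rng.integers(int(np.ceil(r_px)), n_cols - int(np.ceil(r_px))))
                    y_top, y_bot = int(y_epi[col]), int(y_derm[col]) - 1
                    t_plus_1 = y_bot - y_top + 2
                    row = y_top - 1 + d_target * t_plus_1
                    lo = y_top + int(np.ceil(r_px))
                    hi = y_bot - int(np.ceil(r_px))
                    if hi < lo:
                        continue
                    row = int(np.clip(int(np.rint(row)), lo, hi))
                    if all((row - r) ** 2 + (col - c) ** 2 >= sep_px**2 for r, c in centers):
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise ValueError(
                    "could not place blob at requested depth; relax count/separation"
                )
            centers.append((row, col))
            br, bc = _blob_mask(labels.shape, (row, col), r_px, spec.shape, rng)
            dab[br, bc] = np.maximum(dab[br, bc], spec.peak_od)
            # record the actually realized depth of the center row
            d_real = (row - y_top + 1) / t_plus_1
            planted.append(
                PlantedBlob(
                    center_row=row, center_col=col, radius_um=r_um,
                    planted_d_rel=float(d_real),
                    pixels=np.stack([br, bc], axis=1),
                )
            )

    od = (
        counter[..., None] * cfg.basis.counterstain_vector
        + dab[..., None] * cfg.basis.dab_vector
    )
    pixels = od_to_rgb(od, cfg.basis.i0).astype(np.float64)
    if cfg.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, cfg.noise_sd, pixels.shape)
    img = CalibratedImage(np.clip(np.rint(pixels), 0, 255).astype(np.uint8), um)
    truth = PhantomTruth(
        label_mask=LabelMask(labels, um),
        blobs=planted,
        y_top_epi=y_epi.copy(),
        y_bottom_epi=(y_derm - 1).copy(),
    )
    return img, truth


def scribbles_from_truth(
    truth: PhantomTruth, fraction: float = 0.05, seed: int = 0, margin_px: int = 3
):
    """Sparse training scribbles sampled from the ground-truth labels.

    Samples ``fraction`` of the tissue pixels, avoiding ``margin_px`` of
    each band boundary (an operator scribbles in band interiors, not on
    interfaces).
    """
    from scipy import ndimage as ndi
    from .classify import TrainingScribbles

    rng = np.random.default_rng(seed)
    labels = truth.label_mask.labels
    rows_all, cols_all, labs_all = [], [], []
    for cls in (1, 2, 3):
        band = labels == cls
        if margin_px > 0:
            band = ndi.binary_erosion(band, iterations=margin_px)
        r, c = np.nonzero(band)
        n = max(int(round(fraction * r.size)), 1)
        idx = rng.choice(r.size, size=min(n, r.size), replace=False)
        rows_all.append(r[idx])
        cols_all.append(c[idx])
        labs_all.append(np.full(idx.size, cls, dtype=np.uint8))
    return TrainingScribbles(
        np.concatenate(rows_all), np.concatenate(cols_all), np.concatenate(labs_all)
    )
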