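"""Binary tissue masks for the depth metric, plus the partition check.

The relative-depth construction needs two overlapping binary masks derived
from the tissue labels:

* ``inner_mask`` — epidermis plus everything it encloses on the dermis
  side.  Built by flood-filling the non-epidermis complement from a seed
  in the dermis and taking the union with the epidermis.  Filling (rather
  than using the dermis labels directly) absorbs mislabeled islands inside
  the dermis, to which the distance maps are extremely sensitive.
* ``outer_mask`` — the complement of ``inner_mask`` united with the
  epidermis (i.e. outside + squamous + epidermis).

The two masks overlap exactly on the epidermis; their union covers the
image.  This only works when the epidermis forms a sealed band separating
dermis from the outside — ``validate_partition`` checks that requirement
and reports violations instead of producing silently wrong distances.

Connectivity conventions: the flood fill uses 4-connectivity; the
partition check looks for 8-connected leak paths through the complement,
the strictest combination that guarantees a sealed band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import LabelMask, LABEL_OUTSIDE, LABEL_SQUAMOUS, LABEL_EPIDERMIS, LABEL_DERMIS

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class PartitionReport:
    """Outcome of the epidermis-band partition check."""

    ok: bool
    reasons: list[str] = field(default_factory=list)
    #: up to 100 (row, col) pixels on a leaking complement component
    violating_pixels: list[tuple[int, int]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "reasons": list(self.reasons),
            "violating_pixels": [list(p) for p in self.violating_pixels],
        }


@dataclass
class TissueMasks:
    inner_mask: np.ndarray   # epidermis ∪ filled dermis side
    outer_mask: np.ndarray   # outside ∪ squamous ∪ epidermis
    pixel_size_um: float


def validate_partition(mask: LabelMask) -> PartitionReport:
    """Check that the epidermis seals dermis off from outside/squamous.

    PASS requires (a) no 8-connected path of non-epidermis pixels joins a
    dermis pixel to the sample exterior — an outside or squamous pixel on
    the region border — and (b) dermis and epidermis both non-empty.
    Enclosed islands of mislabeled pixels do not fail the check: the
    flood fill in :func:`build_tissue_masks` absorbs them harmlessly,
    whereas a band gap that connects the dermis to the exterior would
    corrupt both distance maps.  FAIL reports reasons and up to 100
    pixels of the leaking component.
    """
    labels = mask.labels
    reasons: list[str] = []
    violating: list[tuple[int, int]] = []
    if not (labels == LABEL_EPIDERMIS).any():
        reasons.append("epidermis empty")
    if not (labels == LABEL_DERMIS).any():
        reasons.append("dermis empty")
    if not reasons:
        complement = labels != LABEL_EPIDERMIS
        comp_labels, n = ndimage.label(complement, structure=_STRUCT_8)
        is_dermis = labels == LABEL_DERMIS
        is_outer = (labels == LABEL_OUTSIDE) | (labels == LABEL_SQUAMOUS)
        border = np.zeros_like(is_outer)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        dermis_comps = np.unique(comp_labels[is_dermis])
        outer_comps = np.unique(comp_labels[is_outer & border])
        leaking = np.intersect1d(dermis_comps, outer_comps)
        leaking = leaking[leaking > 0]
        if leaking.size:
            reasons.append(
                "epidermis band is not sealed: dermis touches outside/squamous "
                f"through {leaking.size} complement component(s)"
            )
            rows, cols = np.nonzero(comp_labels == leaking[0])
            violating = list(zip(rows[:100].tolist(), cols[:100].tolist()))
    return PartitionReport(ok=not reasons, reasons=reasons, violating_pixels=violating)


def dermis_seed(mask: LabelMask) -> tuple[int, int]:
    """Seed pixel for the flood fill: the dermis centroid, snapped to dermis.

    If the centroid pixel is not itself dermis (concave samples), the
    dermis pixel nearest the centroid wins; ties break on smallest row,
    then column.
    """
    rows, cols = np.nonzero(mask.labels == LABEL_DERMIS)
    if rows.size == 0:
        raise ValueError("dermis empty: cannot place flood-fill seed")
    cr, cc = rows.mean(), cols.mean()
    r0, c0 = int(round(cr)), int(round(cc))
    if (
        0 <= r0 < mask.labels.shape[0]
        and 0 <= c0 < mask.labels.shape[1]
        and mask.labels[r0, c0] == LABEL_DERMIS
    ):
        return r0, c0
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    best = d2.min()
    cand = np.nonzero(d2 == best)[0]
    order = np.lexsort((cols[cand], rows[cand]))
    i = cand[order[0]]
    return int(rows[i]), int(cols[i])


def build_tissue_masks(mask: LabelMask, seed: tuple[int, int] | None = None) -> TissueMasks:
    """Construct the inner/outer mask pair from a validated label mask.

    The flood fill runs with 4-connectivity on the non-epidermis
    complement, seeded at :func:`dermis_seed`; every reached pixel joins
    ``inner_mask`` together with the epidermis itself.
    """
    report = validate_partition(mask)
    if not report.ok:
        raise ValueError("partition check failed: " + "; ".join(report.reasons))
    if seed is None:
        seed = dermis_seed(mask)
    epidermis = mask.labels == LABEL_EPIDERMIS
    complement = ~epidermis
    comp_labels, _ = ndimage.label(complement, structure=_STRUCT_4)
    seed_comp = comp_labels[seed]
    if seed_comp == 0:
        raise ValueError("flood-fill seed lies on the epidermis")
    filled = comp_labels == seed_comp
    inner = epidermis | filled
    outer = (~inner) | epidermis
    return TissueMasks(inner_mask=inner, outer_mask=outer, pixel_size_um=mask.pixel_size_um)
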