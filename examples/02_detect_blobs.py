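"""Detect DAB-stained areas on a phantom and measure their depths.

Plants 12 DAB blobs at random depths in the epidermis, runs the
detection chain (OD-sum channel, Gaussian blur, background subtraction
by opening, threshold, connected components, size filter) with its
default parameter block, and compares each recovered blob's mean
relative depth against the planted value.
"""

import numpy as np

from dabdepth import (
    BlobSpec, DetectionParams, SkinPhantomConfig, attach_depths,
    build_tissue_masks, detect_dab_areas, generate_phantom, relative_depth,
)

cfg = SkinPhantomConfig(
    width_um=500, height_um=300,
    blobs=BlobSpec(count=12, depth_distribution=("uniform", 0.15, 0.85)),
    noise_sd=5.0, seed=4,
)
img, truth = generate_phantom(cfg)
field = relative_depth(build_tissue_masks(truth.label_mask), truth.label_mask)
blobs = attach_depths(detect_dab_areas(img, DetectionParams()), field)
print(f"planted {len(truth.blobs)} blobs, detected {len(blobs)}")

errors = []
for planted in truth.blobs:
    center = (planted.center_row, planted.center_col)
    hit = next((b for b in blobs if (b.pixels == center).all(axis=1).any()), None)
    if hit is not None:
        errors.append(abs(hit.mean_d_rel - planted.planted_d_rel))
        print(f"  planted d_rel {planted.planted_d_rel:.3f} -> "
              f"recovered {hit.mean_d_rel:.3f}  area {hit.area_um2:6.1f} um^2")
print(f"mean |depth error|: {np.mean(errors):.4f}  (placement is exact when "
      "the detected area dilates symmetrically around the planted disk)")
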