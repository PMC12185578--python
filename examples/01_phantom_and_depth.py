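"""Generate a skin phantom and inspect the relative-depth field.

Builds a flat-band phantom (blank slide / squamous / epidermis / dermis),
derives the inner and outer tissue masks, computes the two Euclidean
distance maps and the relative depth d_rel = D_top_epi / (D_top_epi +
D_top_derm), and prints the anchor values at the two epidermal
interfaces.  d_rel runs from ~0 where the epidermis meets the stratum
corneum to ~1 at the basal lamina; the residual offset is the one-pixel
discretization 1/(T+1) for a T-pixel-thick epidermis.
"""

from dabdepth import (
    BlobSpec, SkinPhantomConfig, build_tissue_masks, generate_phantom,
    relative_depth, validate_partition,
)

cfg = SkinPhantomConfig(width_um=300, height_um=300,
                        blobs=BlobSpec(count=0), noise_sd=3.0, seed=1)
img, truth = generate_phantom(cfg)
mask = truth.label_mask
print(f"phantom {img.shape[0]}x{img.shape[1]} px at {img.pixel_size_um} um/px")

report = validate_partition(mask)
print(f"partition check: {'PASS' if report.ok else report.reasons}")

field = relative_depth(build_tissue_masks(mask), mask)
col = mask.shape[1] // 2
top, bottom = int(truth.y_top_epi[col]), int(truth.y_bottom_epi[col])
t = bottom - top + 1
print(f"epidermis thickness: {t} px ({t * img.pixel_size_um:.1f} um)")
print(f"d_rel at squamous/epidermis interface: {field.d_rel[top, col]:.4f} "
      f"(limit 0.0, discretization 1/(T+1) = {1 / (t + 1):.4f})")
print(f"d_rel at epidermis/dermis interface:   {field.d_rel[bottom, col]:.4f} "
      f"(limit 1.0)")
print(f"d_rel midline: {field.d_rel[(top + bottom) // 2, col]:.4f} (expect ~0.5)")
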