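# dabdepth

Depth quantification of DAB-stained Langerhans cells across the epidermis
in brightfield immunohistochemistry images.

## The problem

Langerhans cells (LCs) are the epidermis's resident antigen-presenting
cells. On contact with a skin sensitizer they migrate from the stratum
corneum side of the epidermis toward the basal lamina and onward into the
dermis — a key event of the skin-sensitization adverse outcome pathway.
In CD1a immunohistochemistry of skin sections, LCs appear as brown
DAB-stained areas over a red nuclear counterstain. Because LC dendrites
make per-cell counting meaningless in 2-D sections, the readout here is
*where* the DAB signal sits within the epidermis, not how many cells
there are.

`dabdepth` is for toxicologists and image analysts who want that depth
readout reproducibly from calibrated TIFF/PNG sections: tissue-layer
segmentation, a relative-depth coordinate, parameterized DAB blob
detection, and rank-based comparison of depth distributions between
exposure conditions — all validated against synthetic skin phantoms with
known ground truth.

## The method

1. **Tissue segmentation.** A per-dataset random-forest pixel classifier
   labels squamous layer, epidermis and dermis from multiscale
   intensity/optical-density features; near-white pixels become
   "outside". Operator corrections are applied as GeoJSON polygon edits.
2. **Relative depth.** From the labels, two overlapping binary masks are
   built (epidermis∪dermis via a flood fill from the dermis centroid,
   and its complement re-united with the epidermis). Exact Euclidean
   distance maps off each mask give, per epidermis pixel,

   d_rel = D_top-epi / (D_top-epi + D_top-derm)  ∈ (0, 1)

   with d_rel = 0 outside, 1 in the dermis, ≈0 at the
   squamous/epidermis interface and ≈1 at the basal lamina.
   A partition check rejects regions where the epidermis band fails to
   seal the dermis off from the outside (which would corrupt both maps).
3. **DAB detection.** On the optical-density-sum channel: Gaussian blur
   (σ = 2 µm), background subtraction by grayscale opening (disk radius
   20 µm), fixed OD threshold 0.20, 8-connected components, area filter
   5–40 000 µm² — at a working pixel size of 0.6892 µm. Touching areas
   stay merged (no shape splitting).
4. **Statistics.** Per-pixel and per-blob depth distributions, unit-mass
   histograms and unit-area violin densities; unpaired rank-sum
   (Mann–Whitney) comparisons on the full distribution and on the three
   depth bands [0,⅓), [⅓,⅔), [⅔,1]; a KS normality check motivating the
   rank tests.

A synthetic phantom generator renders layered skin cross-sections through
Beer–Lambert optics with DAB blobs planted at controlled depths, so every
stage has a ground-truth oracle.

## Worked example

`examples/02_detect_blobs.py` plants 12 DAB blobs at known depths in a
500×300 µm phantom, runs detection with the default parameter block and
recovers their depths:

```
planted 12 blobs, detected 12
  planted d_rel 0.808 -> recovered 0.809  area  223.2 um^2
  planted d_rel 0.507 -> recovered 0.507  area  281.7 um^2
  ...
mean |depth error|: 0.0001
```

Each line pairs a planted relative depth with the mean d_rel of the
recovered blob: agreement to ~10⁻⁴ because the detected area dilates
symmetrically around the planted disk. `examples/03_compare_conditions.py`
shows the migration readout — a control with superficial blobs versus an
"exposed" condition with basal blobs gives a one-sided rank-sum
p ≪ 0.001, with the signal localized to the deep band. The other
examples cover the depth-field anchors, dose arithmetic and the full
two-stage pipeline; a thin CLI (`dabdepth simulate / train-classifier /
segment / detect / compare / dose / run-all`) wraps the same functions
for shell use.

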