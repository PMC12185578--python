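# Methods

## Scope and model

`dabdepth` quantifies the depth distribution of DAB-positive
(CD1a⁺ Langerhans cell) signal within the epidermis of brightfield IHC
skin sections. The depth coordinate of a pixel is

    d_rel = D_top-epi / (D_top-epi + D_top-derm)

where both distances are exact Euclidean distance transforms: `D_top-epi`
off the *inner* mask (epidermis plus everything the epidermis encloses on
the dermis side) and `D_top-derm` off the *outer* mask (the complement of
the inner mask re-united with the epidermis). The coordinate is 0 on
outside/squamous pixels, 1 on dermis pixels, and strictly inside (0, 1)
on epidermis pixels. It is dimensionless and invariant to the pixel
calibration; absolute distances are also reported in µm.

### Distance conventions

Distances are measured between pixel centers (integer coordinates,
origin top-left, x = column, y = row). An epidermis pixel adjacent to
the squamous interface is therefore 1 px from the nearest outer pixel,
so the denominator of d_rel is at least 2 px and never vanishes; the
interface anchor values are 1/(T+1) and T/(T+1) for a T-pixel-thick flat
band, converging to 0 and 1 as resolution grows. The transform is the
exact Euclidean one (scipy's EDT), not a chamfer approximation, which
makes a brute-force nearest-background search an *equality* oracle in
tests. On flat horizontal bands the field has the closed form
`(y − y_top + 1)/(T + 1)`, used throughout as an independent check.

### Mask topology

The inner mask is built by flood-filling the non-epidermis complement
(4-connectivity) from a seed at the dermis centroid — snapped to the
nearest dermis pixel when the centroid falls outside a concave dermis
(ties break to smallest row, then column). Filling absorbs mislabeled
islands inside the dermis, to which the distance maps are otherwise
extremely sensitive. The construction presumes the epidermis band seals
the dermis off from the sample exterior; `validate_partition` tests this
by 8-connected component analysis of the complement, failing a region
when a component contains both a dermis pixel and an exterior
(border-touching) outside/squamous pixel. Enclosed mislabeled islands
deliberately pass — the fill handles them — while any band gap that
would let the fill leak to the exterior fails before distances are
computed. The 4-connected fill against 8-connected leak detection is the
strictest pairing: any gap an 8-connected path can cross is reported,
and the fill itself can never cross a band that passed the check.

## Stain optics

Per-channel optical density is `−log10(max(I, 1)/I0)` with I0 = 255,
clipped to ≥ 0; the 1-intensity-unit floor keeps saturated pixels
finite. Detection operates on the OD **sum** channel. A two-stain linear
basis (DAB `[0.268, 0.570, 0.776]`, the standard published absorbance
direction, and a red nuclear counterstain `[0.21, 0.85, 0.48]`,
normalized) is used for least-squares unmixing; the unmixed DAB map is a
QC export only, not the detection channel. Both vectors are
configuration values — different counterstain lots warrant refitting —
and how other software chooses its white point and saturation floor is
an implementation constant here, not something the depth metric is
sensitive to (d_rel never touches the optics).

## DAB area detection

The chain, at a working pixel size of 0.6892 µm (images are bilinearly
resampled when their calibration differs by more than one part in 10⁴):

| step | parameter | default |
|---|---|---|
| median filter | radius | 0 µm (off) |
| Gaussian blur | σ | 2 µm |
| background (grayscale opening, disk) | radius | 20 µm |
| background exclusion | max background OD | 2.0 |
| threshold on corrected OD sum | threshold | 0.20 |
| connected components | connectivity | 8 |
| area filter | min / max | 5 / 40 000 µm² |
| shape splitting | | off |
| boundary smoothing | | closing r = 1 px, polygon simplification 0.5 px |

Touching areas are *not* split by shape: Langerhans-cell morphology is
dendritic and per-cell counts in 2-D sections are not meaningful, so
connected DAB areas are the objects of analysis. Blobs are ordered, and
ids assigned, by their topmost-leftmost pixel for determinism. The
background estimator is a grayscale opening — monotone, removes any
structure that cannot contain the structuring disk, and returns exactly
the base level under an isolated blob smaller than the disk.

**Edge dilation.** Thresholding a blurred hard-edged object at a level
well below its peak dilates it: with σ = 2 µm and threshold at ~12% of a
unit-DAB blob's corrected peak, the detected contour sits ≈ 2.3 µm
outside the true edge (the Gaussian edge profile crosses 0.12 of its
plateau at ≈ 1.15 σ beyond the boundary). Detected areas of phantom
disks therefore exceed the planted areas by a predictable margin — the
unit tests pin the detected area to this dilation oracle rather than to
the planted area. The dilation is symmetric, so blob *centroids* and
mean depths are essentially unbiased (phantom recovery shows mean
absolute depth error ~10⁻⁴ on flat bands); real diffuse-edged chromogen
deposits dilate less than the worst-case hard disk.

## Tissue classifier

A random forest (50 trees, depth ≤ 12, fixed seed) on 7 features per
scale — R, G, B, three per-channel ODs and the OD sum, Gaussian-smoothed
at 1, 2 and 4 µm — trained on sparse operator scribbles covering all
three tissue classes. Prediction is per-pixel argmax followed by
majority smoothing in a disk of radius 2 px; pixels with OD sum < 0.05
are forced to "outside", which is a derived whiteness class rather than
a trained one (blank slide is not tissue and needs no examples). The
classifier is intentionally per-dataset: staining protocols vary too
much for pretrained weights to be trustworthy, so none ship. Equivalence
with other segmentation tools is defined at the level of the downstream
depth metrics, not per-pixel labels.

## Depth statistics

Distributions are kept both per *pixel* (each DAB-positive pixel
contributes; large areas weigh more) and per *blob* (one mean per area);
the two means coincide exactly when all blobs have equal area.
Histograms over [0, 1] (default 50 bins) are normalized to unit mass and
violin densities to unit area, so shapes compare across conditions with
different pixel counts. Per-replicate histograms are also emitted; their
bin-wise mean is the mean-of-replicates curve.

Comparisons use the unpaired two-sample rank-sum (Mann–Whitney) test —
pixel populations from different sections are independent, so a paired
signed-rank design does not apply. p-value computation: scipy's exact
method for tie-free samples with n, m ≤ 50; full enumeration of group
assignments when ties are present and C(n+m, min(n,m)) ≤ 2·10⁵ (exact
even under ties, at the only sizes where enumeration is tractable);
otherwise the tie-corrected normal approximation with continuity
correction. The "three equal parts" analysis splits the *depth axis*
into [0, ⅓), [⅓, ⅔), [⅔, 1] — depth bands, not equal-count terciles —
because the question is where on the migration path the signal moved; a
band left empty by one group is flagged "insufficient data" rather than
erroring. The KS normality check fits the normal by moments, which makes
its p-value conservative (parameters estimated from the data); it is
used only to justify the switch to rank tests. Significance is declared
at p < 0.05 everywhere.

## Synthetic phantoms

The generator renders what the analysis consumes and nothing more:
horizontal bands (blank slide, squamous, epidermis, dermis) with
optional sinusoidal interface undulation, a fast-red-like counterstain
at band-specific concentrations (0.25 / 0.55 / 0.35 OD multipliers),
and DAB disks (optionally star-shaped) planted at target relative
depths converted to rows through the flat-band closed form. Rendering
adds stain ODs linearly and exponentiates (Beer–Lambert), so unmixing
is exactly invertible before noise; Gaussian read noise (default
sd 5 intensity units) is added last. Defaults: 0.6892 µm/px, 500 µm
square regions, 20 µm squamous and 100 µm epidermis, blob radii
5–8 µm at peak DAB OD 1.0, ≥ 30 µm center separation (relaxed stepwise
down to bare non-overlap when a depth line is crowded; recovery suites
use a 1600 µm-wide phantom so 50 blobs place comfortably). Same seed,
same bytes.

What the phantoms do **not** emulate: real rete-ridge geometry beyond a
sinusoid, dendritic LC morphology (blobs are compact), stain variation
within a section, chromatic aberration, folds and cuts. Passing the
phantom suites therefore demonstrates the *computational* chain —
segmentation-to-depth-to-statistics correctness, parameter semantics,
determinism — not robustness to histology artifacts, which is why the
pipeline keeps the operator refinement and partition-validation steps
in the loop for real slides.

## Exposure dosimetry

For aqueous solutions 1 ppm ≡ 1 mg/L. Applying 20 µL of a c g/L
solution delivers 20·c µg; dividing by the 8 mm insert footprint
(π·16 mm²) gives the areal dose in g/m². Values are carried at full
precision with a 2-significant-figure display column, since printed
dose tables round inconsistently (truncation vs rounding in the last
digit); comparisons against printed values accept ±1 unit in the last
printed digit.

## Problem sizes and numerical choices

Test and example phantoms are 250–500 µm squares (≈ 360–730 px);
recovery suites use 1600×400 µm with 50 blobs. The EDT-vs-brute-force
equality check runs 200 random masks up to 64×64 (the oracle is
O(N²)). Rank-sum calibration uses 500 null replicates at n = 60 per
group. Degenerate inputs are handled explicitly: all-true masks are an
error for the EDT (no background to measure from), empty blob lists are
valid empty distributions, constant samples get a 10⁻¹² scale floor in
the normality check, and polygon rasterization tests pixel *centers*
so half-open boundary behavior is deterministic.

## Known limitations

- Depth is 2-D within the section plane; out-of-plane migration is
  invisible, and dermal LC burden is out of scope.
- Multi-fragment sections with several disjoint epidermis bands per
  region are not supported; choose regions that contain one band.
- The detector's low threshold relative to typical DAB peaks
  over-segments object *area* (edge dilation above); area-sensitive
  analyses should calibrate against the blur/threshold pair.
- The classifier transfers poorly across staining protocols by design;
  retrain per dataset.
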