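# Methods

## Scope and model

`lumenquant` quantifies the cross-sectional shape and contrast enhancement
of the flow channels of a dissected aorta on an axial CT-angiography
stack. The analysis is strictly per-slice (2-D): each slice is segmented,
its duct masks measured, and series statistics are built over slices. No
3-D surface reconstruction, centerline extraction, or hemodynamic
simulation is performed.

Intensities are treated as raw pixel values throughout, not Hounsfield
units: all brightness quantities (B_AV, BI, CNR, inter-duct differences)
are either ratios or are only ever compared within/between regions of the
same acquisition, so an affine recalibration cancels (CNR is exactly
invariant under intensity maps a·x + b with a > 0; B_AV maps to
a·B_AV + b).

## Segmentation

The segmentation chain is the classic contrast-CT recipe:

1. **Windowing** (optional): clip to [low, high], rescale linearly. Only
   monotone, so it never reorders in-window intensities; the default
   output range equals the window width so tolerances keep their units.
2. **Seeded region growing**: a region grows from seed pixels to every
   4-connected pixel whose intensity lies within `tolerance` of the
   *running mean* of the grown region (mean updated after each accepted
   frontier shell). The running-mean criterion tolerates slow axial
   contrast gradients that a fixed seed-value criterion would not.
   4-connectivity is used everywhere (growing, labeling) because the
   intimal flap is thin: 8-connectivity could leak diagonally across a
   one-pixel flap.
3. **Hole filling**: `scipy.ndimage.binary_fill_holes` per slice
   (idempotent; background components not connected to the border are
   filled).
4. **Duct labeling**: one connected component ⇒ common duct; two ⇒
   true/false, assigned by mean brightness (false = brighter, matching
   the physiology of preferential false-lumen filling) or optionally by
   area (false = larger). Once both ducts exist, labels propagate to the
   next slice by maximal pixel overlap so a transient fluctuation cannot
   swap them. More than two components is an error naming the slice.
   Component-count changes are recorded as split (1→2) and merge (2→1)
   transitions at the first slice with the new count.

Seeds are required on one slice only; masks propagate both directions
through the stack. The next slice's seed set is the previous mask eroded
by one pixel and filtered to pixels within `tolerance` of the median
intensity over that footprint — the median filter matters at a split,
where the parent lumen's footprint covers the new (dark) flap whose
pixels must not pollute the region mean. Both daughter lumens inherit
seed pixels from the parent footprint, so splits need no new seeds.

Default `tolerance` is 60 pixel-value units: comfortably above the noise
(6σ at the default noise SD 10) and comfortably below the smallest
barrier contrast (lumen-to-flap gap ≥ 90 at the default enhancements), so
boundary misclassification requires a ≥ 6σ noise excursion.

## Geometry

- **Extents**: inclusive pixel span, (max − min index + 1) × spacing, so
  a single pixel has extent one spacing. Feret diameter is the mean of
  the vertical and horizontal extents (axis-aligned by definition — this
  is not the rotating-calipers maximal Feret diameter).
- **Area**: pixel count × pixel area.
- **Perimeter** (the denominator of the hydraulic diameter): measured on
  the marching-squares 0.5-level contour of the zero-padded mask, but not
  on the raw polygon — the raw marching-squares length overestimates
  digital straight edges at intermediate orientations by up to +8%
  (≈ +6% averaged around a circle) and clips right-angle corners by
  ≈ 0.29 px each. The estimator therefore post-processes each closed
  contour:
  1. a circular moving average (window 5 vertices) gives the smooth-arc
     polygon, essentially unbiased on curves (+0.4% or better for disks
     of radius ≥ 10 px);
  2. zones where the turning accumulated over ±2 smoothed segments
     exceeds 60° are treated as corners: the zone polyline is replaced by
     the intersection of principal-direction line fits to the 5 raw
     vertices flanking each side, which restores rectangle corners
     exactly (intersection accepted only when it lies forward of both
     zone ends and within 15 px; otherwise the raw polyline is kept);
  3. zones turning by more than 100° (cusps, thin slivers such as
     crescent tips) keep the raw contour, which tracks them best;
  4. contours with fewer than 15 vertices, or with over 70% of vertices
     in corner zones, fall back to the raw polyline.
  Validation against closed forms: exact on pitch-aligned rectangles,
  ≤ 0.4% on disks of radius ≥ 10 px, −0.06% on a 2:1 ellipse, within
  2.3% of exact boolean-geometry perimeters for the phantom's crescents.
- **Degenerate inputs**: empty masks are rejected everywhere with
  explicit errors; a duct expected on a slice but segmented empty becomes
  a flagged NaN row in the measurement table rather than a crash.
- Shapes whose dimensions are not integer multiples of the pixel pitch
  quantize to whole pixels (up to ~1 px per side); that is a resolution
  limit of any raster representation, not of the estimators, and is why
  estimator validation uses pitch-aligned rectangles.

## Brightness and image quality

B_AV is the plain mean over the mask. Lumen ROIs are disks of 80 mm²
placed at the duct centroid (recentered to the interior point farthest
from the boundary when the centroid falls outside a crescent); background
ROIs are two 100 mm² disks outside the body, left and right. Noise is the
root mean square of the two ROIs' within-ROI sample SDs — pooling spreads
rather than pooled pixels, so a constant left/right offset does not
inflate the estimate. BI and CNR divide by this SD and are deliberately
rejected (not returned as inf) when the noise estimate is zero, which on
real data only happens when the ROIs were misplaced.

The "centered ROI" reading of lumen brightness placement is one of two
defensible conventions (the other being the ROI position that maximizes
mean intensity); the centered one is the default because it is
reproducible without an optimization step.

## Difference series and summaries

The per-slice inter-duct difference is normalized:
|x_i − x_j| / max(x_i, x_j), dimensionless in [0, 1] and invariant under
common rescaling of both series; the raw signed difference in native
units is carried alongside. The printed forms of the underlying
difference definitions are typographically self-subtracting, so the
normalization constant is a package design decision, chosen to land the
statistic in the unit interval where the reference values for it live.
All mean ± SD summaries use the sample SD (n − 1); n = 1 yields SD 0 with
n reported. Cross-patient duct gaps are |mean_i − mean_j| per patient,
summarized over patients the same way; with the published three-patient
brightness means this reproduces the published gap statistics to the
printed two decimals (residuals ≤ 0.007 traceable to the inputs
themselves being rounded to two decimals).

## Agreement statistics

Bland–Altman uses the fixed 1.96 multiplier (not a t-quantile):
bias = mean difference, limits bias ± 1.96·SD(diff), "range" = width of
the limits = 2·1.96·SD, and the outside count is the number of pairs
whose difference falls outside the limits — each pair being one slice's
(D_F, D_Hy). Spearman correlation (average ranks on ties, two-sided p)
and Mann–Whitney U (tie-corrected; exact p for small tie-free samples)
are thin, contract-checked wrappers over scipy, with constant-input and
empty-sample cases turned into explicit errors.

## The phantom: what it emulates, and what it does not

The generator emulates the *topology and enhancement structure* of a
type B dissection on CTA: a single bright lumen that splits into two
channels separated by a dark flap and merges back, with per-region mean
enhancement and i.i.d. additive Gaussian noise. Geometry per dissected
slice: common duct = disk of radius R (default 15 mm); true lumen = disk
of radius 0.45·R tangent to the outer wall (the compressed true channel
hugs the wall); flap = a ring of thickness 2 mm around the true lumen;
false lumen = the remaining crescent. The default grid is 128 × 128 × 140
voxels at 0.78 × 0.78 × 0.8 mm — the published acquisition's voxel
spacing with a shortened axial extent that keeps a full
common→split→merge→common cycle (split at slice 40, merge at 100) while
keeping default runs fast. Default enhancements (background 30, flap 60,
true 150, common 180, false 200; noise SD 10) encode the reference
ordering false > common > true at magnitudes in the range of reported
single-patient enhancement values, with noise at most 10% of the
smallest lumen/background contrast gap.

Deliberately absent, and therefore *not* validated by passing tests on
phantom data: partial-volume blur at boundaries (phantom edges are
crisp, which is why segmentation recovers ground truth to 2–3% rather
than the larger errors real boundary blur would cause), beam hardening
and streak artifacts, intra-lumen enhancement gradients (bolus timing),
cardiac/respiratory motion, anatomical curvature of the aorta (the
phantom is a straight tube), and thrombus inside the false lumen. Results
on real CTA should be expected to degrade accordingly, most of all at the
segmentation stage.

Determinism: one `numpy` generator seeded from the config; identical
configs give bit-identical volumes, and the end-to-end pipeline rerun
with the same config reproduces every output file byte-for-byte (DICOM
UIDs are derived deterministically from the seed and the content date is
fixed).

DICOM export stores rounded uint16 pixels (slope 1, intercept 0), exact
for integer-valued non-negative volumes such as noiseless phantoms and
lossy below half a pixel-value unit otherwise; the `.npz` + JSON bundle
is the lossless container. The reader records whether a rescale
slope/intercept was applied, since brightness in raw "pixels" is
convention-dependent on that point.

## Problem sizes used in the validation suite

The bundled validation runs use 20 phantoms of 96 × 96 × 40 voxels for
segmentation recovery and ordering properties (the dissected range spans
slices 10–30), 20 phantoms at the full 128 × 128 × 140 default geometry
for the from-scratch acceptance recomputation, and 10⁴ simulated pairs
for the Bland–Altman tail property. These sizes give stable statistics
(the recovery maximum is taken over 4 000 slice/duct comparisons) while
keeping the whole suite around ten seconds.

## Known limitations

- The per-slice measurement series are spatially autocorrelated along the
  stack; Bland–Altman limits and test p-values treat slices as
  independent pairs, as is conventional, so they are optimistic on
  strongly correlated stacks.
- The Feret diameter is axis-aligned by definition; masks rotated
  in-plane change D_v/D_h (and hence D_F) even when the shape is rigid.
- The brightness-based true/false disambiguation assumes the false lumen
  is the brighter channel; in late-phase acquisitions or thrombosed false
  lumens that assumption fails and the area rule or manual labels must be
  used.
- Region growing is per-slice with footprint propagation; a duct that
  disappears completely for several slices (occlusion) breaks the
  propagation chain for that duct and produces flagged empty rows rather
  than re-detection.
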