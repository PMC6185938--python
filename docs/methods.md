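# Methods

## Image model and conventions

Images are `(channel, z, y, x)` grids of non-negative real intensities with
an isotropic in-plane pixel size in µm/pixel. Coordinates are 0-based,
row-major `(y, x)` with the origin top-left. Anisotropic calibration is
rejected rather than averaged, because every length formula assumes a single
scale. On-disk bit depth (8/16-bit integer or float) is irrelevant
internally; quantile thresholds make the segmentation depth-agnostic.
Z-stacks are reduced to 2D working images by maximum-intensity projection,
applied to both the cilium and the nuclear channel; all morphometry is 2D.

## Segmentation chain

**Hysteresis dual thresholding.** Foreground is every pixel strictly above
the low threshold that is 8-connected, through pixels strictly above the
low threshold, to at least one pixel strictly above the high threshold.
Strict inequality means a constant image equal to the threshold segments to
nothing, and `hysteresis(t, t)` degenerates to a simple strict threshold.
8-connectivity is used throughout because cilia are thin, frequently
diagonal structures that 4-connectivity fragments. Thresholds are given
either as absolute intensities (calibrated acquisitions) or as per-image
empirical quantiles. Quantile resolution is per image, not global, since
staining and illumination vary between fields.

Default quantiles: cilia (0.99, 0.999), nuclei (0.80, 0.99). The cilia
defaults sit far out in the tail deliberately: cilia typically cover well
under 1% of a field, so a lower high-quantile would land inside the noise
distribution and seed spurious objects. Quantile thresholds always leave
`(1−q)·N` pixels above them; the minimum-area filter is what removes the
resulting isolated noise detections. All four resolved values are logged
per image.

**Size filter.** 8-connected components with fewer than
`min_object_area_px` pixels are removed (5 px for cilia at 0.1 µm/px,
50 px for nuclei). The operation is idempotent and never adds foreground.

**Watershed splitting.** Touching objects are split by flooding the negated
Euclidean distance transform, restricted to the mask. Seeds are obtained by
morphological reconstruction of `(distance − 1)` under the distance map
(shifted by +1 inside the mask so 1-px-wide objects stay above the
background plateau), whose regional maxima merge any peaks separated by
dips shallower than 1 px. This choice matters for curvilinear objects: the
distance ridge of a thin cilium is essentially flat, so coordinate-based
peak picking would scatter many seeds along one cilium and shred it,
whereas the plateau of the reconstruction yields exactly one seed. Two
fused convex nuclei still produce two seeds because the saddle between
their distance peaks is deeper than 1 px. Seed regions whose centroids lie
closer than `split_min_distance_px` (and that belong to the same connected
component) are merged before flooding. Output labels are renumbered 1..N in
raster order, making the full chain bit-deterministic.

## Length estimation

The per-cilium length is the longest geodesic path along the object's
1-px skeleton, counting 1 per axial and √2 per diagonal step, scaled by the
pixel size. The path search runs Dijkstra from every skeleton endpoint
(degree ≤ 1 node), which is exact for the tree-shaped skeletons thinning
produces for simple elongated objects; a cyclic skeleton falls back to a
double-sweep approximation. No endpoint correction is applied: under
realistic blur, thresholding extends the object past its true ends by about
as much as skeletonization retracts it, so the two biases largely cancel.
Validation on rendered cilia of known arc length (2–6 µm, 0.1 µm/px, blur
0.15 µm, peak SNR 10) gives a mean absolute relative error of ~8%. The
ellipse major-axis length is reported alongside as `major_axis_um` for
users who prefer a chord-like metric; it underestimates curved cilia.

Single-pixel objects have length 0; the length of any object is bounded by
`area_px × pixel_size × √2`.

## Incidence and field summaries

Incidence is cilia count / nuclei count × 100 for the same region. Fields
with zero detected nuclei report a missing incidence plus the
`no_nuclei_detected` flag; incidence above 100% is reported unclamped with
the `multiciliation_or_oversegmentation` flag, since in this assay it
almost always signals segmentation failure rather than biology. The
per-image cilia length is the arithmetic mean over all cilia in the image
(missing when none).

## Statistics

Groups are summarised as mean ± SEM (sample sd / √n; missing at n = 1).
One-way ANOVA uses the classical between/within decomposition with p from
F(k−1, N−k); degenerate all-equal input returns F = 0, p = 1. Dunnett's
many-to-one comparisons use pooled-variance t statistics and adjusted p
values from the equicorrelated multivariate-t null (correlation derived
from group sizes; ½ when balanced), evaluated by seeded quasi-Monte-Carlo
integration so repeated runs are identical; with a single treatment the
adjustment is vacuous and the adjusted p is computed exactly as the pooled
two-sided t-test p. Adjusted p values are floored at the raw pairwise p.
All tests are two-sided. Either per-field values (default) or pooled
per-cilium lengths can feed the tests; the choice is recorded in the
report, since field means and individual cilia answer subtly different
questions about variability.

QC rules annotate, never block: minimum 150 cilia per sample, 300 cells
per sample, 100 cells per population, more than 10 fields of view.

## Synthetic micrographs

The simulator emulates the analysed fields, not any particular microscope.
Defaults per field: 512×512 px at 0.1 µm/px; 25 non-overlapping elliptical
nuclei of 3 µm mean radius with ±25% axis asymmetry; ciliation probability
0.7; cilium arc lengths log-normal with median 3.5 µm and geometric sd
1.25, chosen so the arithmetic sd is ≈0.8 µm at that median; cilium paths
are fixed-step (0.05 µm) random walks with per-step turning uniform in
±0.15 rad, giving a minimum turning radius of ~0.33 µm so paths do not
self-cross; strokes are rasterised ~1 px wide with bilinear anti-aliasing
and max-blending; cilia anchor just outside a nucleus border, heading
outward, and are kept ≥3 px from each other so clean-regime counts are
exact by construction. Optics and camera: Gaussian blur of 0.15 µm,
renormalised so the configured intensities are peak amplitudes above the
constant background (default 100), Poisson shot noise on expected counts,
additive Gaussian read noise (sd 10). All randomness flows from one seeded
generator; per-field seeds in multi-group experiments are spawned from the
master seed, so outputs are byte-reproducible.

What the simulator does *not* emulate: organoid tissue texture and
autofluorescence, out-of-focus haze from true 3D stacks (z-extent is 1),
nucleus clustering and overlap (available only via an explicit overlap
mode used to exercise watershed splitting), photobleaching, and basal-body
markers. Passing the ground-truth tests therefore demonstrates correctness
of the measurement chain under a fair camera model, not robustness to every
artefact of real tissue imaging.

## Problem sizes used in validation

The shipped validation runs use sizes chosen to exercise every code path
at desk scale: 200 random 32×32 images against the flood-fill oracle;
100–200 rendered cilia for length recovery; 5–10 full fields for exact
count recovery; 200–500 null replicates (3 groups × n = 30) for test
calibration; 100 replicate experiments of 150 cilia per group for effect
recovery. Larger studies change none of the code paths, only runtime.

## Known limitations

- Lengths are measured on 2D projections; cilia steeply inclined to the
  imaging plane are foreshortened. A 3D (through-z) length is out of scope.
- Cilia are not assigned to specific nuclei, so incidence is a field-level
  ratio, not a per-cell classification.
- The watershed contract guarantees only the generic behaviour (labels
  partition the mask; single-peak components stay whole); heavily fused
  clusters of more than two nuclei may split imperfectly.
- Quantile thresholds assume sparse bright structures; images dominated by
  foreground need absolute thresholds.
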