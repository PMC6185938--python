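# ciliaquant

Quantification of primary-cilium morphology from multi-channel fluorescence
micrographs: per-cilium length, per-field ciliation incidence, and
control-referenced group statistics — together with a synthetic micrograph
simulator that provides exact ground truth for validating every stage.

## The scientific problem

The primary cilium is a single microtubule-based sensory protrusion present
on most cell types; its length and its presence per cell (incidence) are
standard read-outs of ciliogenesis. In disease models — for example
retinitis-pigmentosa patient-derived RPE cells and retinal organoid
photoreceptors — both read-outs are compared between patient and control
lines. Images carry a cilium marker (typically ARL13B) and a nuclear stain
(DAPI); the analysis must detect dim, thin, curved cilia against background,
count nuclei even when they cluster, and turn the per-image measurements
into defensible group comparisons.

`ciliaquant` implements that workflow as a tested, reusable Python library:

1. **Input** — TIFF / OME-TIFF (axes `CYX` or `CZYX`), physical pixel size
   from OME metadata or a user override; z-stacks reduced by
   maximum-intensity projection.
2. **Segmentation** — hysteresis dual thresholding: pixels strictly above
   the upper threshold *t*<sub>hi</sub> seed objects, and 8-connected pixels
   strictly above the lower threshold *t*<sub>lo</sub> are appended, which
   suppresses isolated noise pixels; objects smaller than a minimum area are
   removed; clustered objects are split by watershed on the Euclidean
   distance transform with h-maxima seeds.
3. **Morphometry** — per object: pixel area, mean intensity over the
   original image, centroid, and two length estimates in µm: the longest
   geodesic path along the 1-px skeleton (1 per axial, √2 per diagonal
   step) and the ellipse major-axis length. Per field: cilia count *C*,
   nuclei count *N*, mean cilium length, and incidence = *C*/*N* × 100%.
4. **Statistics** — mean ± SEM per group, one-way ANOVA, Dunnett's post hoc
   test of each group against a named control (family-wise error controlled
   on the equicorrelated multivariate-t null), two-sided t tests, and
   minimum-count QC rules (≥150 cilia and ≥300 cells per sample, ≥100 cells
   from >10 fields).

The simulator renders fields of non-overlapping elliptical nuclei with
attached curvilinear cilia of known log-normal arc length, under Gaussian
point-spread blur, Poisson shot noise and Gaussian read noise, and emits the
ground truth for every object drawn.

## Worked example

`examples/03_group_comparison.py` simulates a control group (median cilium
length 3.5 µm, 70% ciliation) against a patient group (2.5 µm, 40%), runs
the full measure → stats chain, and prints:

```
measured 94 cilia over 8 fields

mean_length_um
  control: 3.68 +/- 0.05 um (mean +/- SEM, n=4 fields)
  patient: 3.04 +/- 0.16 um (mean +/- SEM, n=4 fields)
  patient vs control: t = -3.83, adjusted p = 8.65e-03 **

incidence_pct
  control: 70.00 +/- 4.08 % (mean +/- SEM, n=4 fields)
  patient: 47.50 +/- 4.79 % (mean +/- SEM, n=4 fields)
  patient vs control: t = -3.58, adjusted p = 1.17e-02 *
```

The negative t statistics with small Dunnett-adjusted p values report the
simulated reductions in both length and incidence; stars follow the
conventional mapping (\* < 0.05, \*\* < 0.01, \*\*\* < 0.001,
\*\*\*\* < 0.0001). The other example scripts demonstrate field simulation,
single-image measurement, and validation of the length estimator.

A thin CLI wraps the same functions for shell use:

```bash
ciliaquant simulate --out data/ --seed 1 --n-fields 4
ciliaquant measure  --config run.yaml --out results/
ciliaquant stats    --config run.yaml --control control
ciliaquant report   --config run.yaml        # label overlays for visual QC
```

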