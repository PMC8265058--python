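# Methods

## The measurement

The quantity of interest is the box-counting fractal dimension (FD) of
the trabeculated endocardial border on each end-diastolic short-axis
slice. For a one-pixel-wide binary border, grids of cell size `s` are
overlaid and the number `N(s)` of occupied cells recorded; FD is the
slope of the ordinary least-squares fit of `log N` on `log(1/s)`. A
smooth closed contour yields FD ≈ 1; increasing trabecular complexity
raises FD toward (but never reaching) 2, so every valid endocardial
measurement lies in the open interval (1, 2).

Numerical choices:

* **Box-size schedule.** Geometric with ratio 2^(1/4) (four sizes per
  octave), from 2 px up to 45 % of the short side of the border's
  bounding box. The dense schedule stabilizes the regression on small
  hearts; the upper cap keeps the largest boxes informative.
* **Grid phases.** For each size, counts are minimized over a 3×3 grid
  of third-of-cell offsets. This suppresses grid-alignment bias and
  keeps the estimate stable under few-pixel translations (measured
  |ΔFD| ≈ 0.01 for ≤ 3 px shifts); it was preferred over a four-phase
  half-cell scheme, which left translation sensitivity at ≈ 0.02.
* **Monotone envelope.** With non-nested, offset-minimized grids a
  coarser grid can occasionally beat a finer one by a cell; counts are
  clamped to be nondecreasing as boxes shrink before fitting, which is
  the meaningful covering number.
* **No scaling-window selection.** All scheduled sizes enter the fit;
  the fit's R² is reported per slice for quality control.
* FD is computed on the pixel grid. Dimension is scale-free, so pixel
  spacing never enters the FD itself; physical units (mm) are used only
  for segmentation geometry and the comparator indices.

Stack aggregation: global FD is the mean and maximum FD the maximum of
the included per-slice FDs. The most apical slice is always excluded
(partial-volume artefact); slices with empty or non-converged
segmentations are excluded and logged. The included slices are
partitioned into contiguous basal/mid/apical thirds of `floor(n/3)`
slices each, remainder assigned first to mid then to apical, and the
per-third maxima reported. Fewer than three included slices is an
error, not a silent degradation.

## Segmentation

The border is delineated within a region of interest (ROI) around the
blood pool: automatically (Otsu threshold, largest connected bright
component, filled and dilated by a 3 mm margin) or from a supplied
polygon/prior mask. A two-phase piecewise-constant (Chan–Vese style)
level set evolves from the ROI shrunk inward, in chunks of five
iterations until fewer than 0.1 % of pixels change phase (cap 200).

Two deliberate choices depart from common level-set defaults:

* **Zero boundary-length penalty (`mu = 0`) by default.** At ~1.8 mm
  resolution, trabecular detail lives at one or two pixels; even a mild
  curvature penalty erases it and collapses FD toward a smooth
  contour's value (~1.0), destroying exactly the signal being measured.
  With `mu = 0` the exact minimizer of the energy is the pointwise
  two-means assignment, so after the morphological evolution converges
  the mask is refined by reassigning pixels from the converged region
  means. `mu` stays configurable for low-SNR data, as does a speckle
  cleanup size (`min_feature_px`, default 0 — off).
* **The contour band.** The evolving contour is confined to the ROI
  dilated by `contour_band_mm` (5 or 10 mm in practice). With a tight
  subendocardial ROI, the 5 mm setting cuts off the floor of recesses
  deeper than 5 mm that the 10 mm setting retains — the two settings
  genuinely change the edge map on deeply trabeculated slices. The
  band's semantics (an evolution corridor around the ROI) is this
  package's interpretation of a "contour width" parameter whose exact
  meaning semi-automated tools leave unspecified; it is recorded here
  and exposed in configuration.

The edge map is the 8-connected morphological inner boundary of the
mask (erosion by the 4-connected cross), one pixel wide on straight
runs. Segmentation is fully deterministic.

## The phantom generator

Phantoms emulate the features the analysis depends on, not MRI physics:
SSFP-like two-level contrast (bright blood 0.85, dark myocardium 0.15)
with optional additive Gaussian noise (default σ = 0.04); 256×256 px at
1.8 mm; 10 slices of 8 mm with a 2 mm gap; base endocardial radius
40 mm tapering linearly to 40 % at the apex.

The trabeculated border is a radial Fourier perturbation

```
r(θ) = R0 · (1 + A · Σ_k c_k k^(−β/2) cos(kθ + φ_k)),   k = 2 … 97
```

with seeded normal coefficients and uniform phases, normalized to unit
peak so that the amplitude `A ∈ [0, 0.5]` bounds the relative radial
excursion. The radial parameterization guarantees a simple polygon;
`A = 0` gives an exact circle. `A` is the single monotone roughness
knob (rank correlation with measured FD ≥ 0.96 across amplitudes);
the spectral exponent β (default 1.0) shapes the texture.

**Group presets.** Three presets encode the cohort structure of
pediatric trabeculation studies: noncompaction (highest roughness,
nondecreasing base→apex, thin 4 mm compacted wall), hyper-trabeculated
(intermediate roughness, mid-ventricular peak, 5.2 mm wall), normal
(lowest roughness, mid-ventricular peak, 8 mm wall). The per-slice
amplitude is the preset's base amplitude times an axial multiplier
table. The tables were calibrated once, by inverting the empirically
measured FD-versus-(amplitude, radius) response of the full pipeline,
so that each preset realizes a well-separated per-slice FD profile in
which (a) every slice stays strictly above FD 1 after rasterization and
segmentation, (b) the noncompaction preset peaks apically and the other
two mid-ventricularly, and (c) group mean global FD orders
noncompacted > hyper-trabeculated > normal with roughly two
within-group standard deviations between adjacent groups. Absolute FD
values are deliberately *not* calibration targets; orderings are.

Ground truth shipped with every phantom: per-slice cavity masks (the
segmentation target), total-myocardium and compacted-layer masks for
the mass-fraction index (epicardium = trabecular envelope + wall), and
noncompacted/compacted thickness pairs for the layer-ratio index (the
noncompacted thickness is proxied by the mean trabecular protrusion
depth below the compacted envelope).

**What the phantom does not emulate.** No papillary muscles as separate
structures, no long-axis views, no k-space or motion artefacts, no
partial-volume blur (the rasterization is a hard two-level image — this
is why segmentation recovers ground truth essentially exactly, and why
passing Dice tests say nothing about contrast-limited real data). The
roughness needed to keep every slice's FD resolvably above 1 at 1.8 mm
also inflates the trabecular mass fraction well beyond clinical values
(the mass-fraction index classifies *all* presets as noncompacted);
mass-fraction threshold behavior is therefore exercised on explicit
mask fixtures, and only the between-group *ordering* of the fraction is
meaningful on phantoms. Likewise the rasterization ceiling (FD ≈ 1.3 at
apical radii) compresses the noncompaction preset's top end, so maximum
FD separates the noncompaction group strongly but not completely —
real cohorts report complete separation, which the phantom does not
claim to reproduce.

## Known-dimension oracles

The estimator is validated against curves of analytic Hausdorff
dimension rasterized one pixel wide: circle and line segment (FD 1),
the Koch curve at 5 iterations (log 4/log 3 ≈ 1.2619) and the
Sierpinski triangle at 6 iterations (log 3/log 2 ≈ 1.585), at 1024 px.
Measured values land within ±0.05 of theory; the residual bias is
rasterization- and finite-iteration-limited, not a property of the
counting.

## Comparator indices

The layer-ratio criterion takes paired noncompacted/compacted
thickness measurements (ground truth or manual entry; automating
long-axis landmarking is out of scope) and records the *largest* ratio:
≥ 2.3 noncompacted, ≥ 1.8 and < 2.3 hyper-trabeculated, else normal
(boundaries inclusive exactly as published). The mass-fraction
criterion subtracts compacted from total mass — per-slice area ×
(thickness + gap) × 1.05 g/mL (standard myocardial density; the
thickness-plus-gap slice volume is the contiguous-coverage convention,
both configurable) — and classifies noncompaction strictly above 20 %.
The "trabeculations could not be defined" fallback of manual readings
is an explicit per-slice flag for the user; it is never inferred.

## Statistics

* ICC is fixed to the two-way random-effects, absolute-agreement,
  single-measurement form ICC(2,1) — the standard observer-agreement
  choice; this matters because ICC variants differ numerically, so the
  form is stated prominently. CIs use the standard F-distribution
  bounds; the implementation is cross-checked against an independent
  package and a brute-force variance-component oracle in the tests.
* Bland–Altman limits use 1.96 × sample SD of the paired differences
  (the classical method, not a t-quantile).
* ROC is empirical; AUC by the trapezoid rule (equal to the
  concordant-pair fraction with ties counted half, asserted against a
  brute-force oracle); the Youden threshold maximizes
  sensitivity + specificity − 1 over observed thresholds, ties broken
  toward the higher threshold.
* Exact binomial CIs are Clopper–Pearson by beta-quantile inversion
  (no mid-p variant); coverage is verified ≥ nominal on a seeded
  simulation grid.
* Group comparisons: for two independent groups the rank-sum
  (Mann–Whitney) test is computed — observer-study tables sometimes
  label this comparison a signed-rank test, but the signed-rank test is
  a paired procedure and would be incoherent for independent groups;
  both tests are available, the pipeline defaults to rank-sum (exact
  for combined n ≤ 20 without ties). Welch's t and Pearson correlation
  round out the battery. No multiple-testing correction is applied;
  raw p-values are reported with that caveat.
* Cohort summaries report mean (SEM) and median (IQR) side by side
  rather than choosing one.

## Observer-variability emulation

No second human exists in CI, so repeat-run agreement is emulated. ROI
vertex jitter alone is a no-op here: the final mask is the pointwise
bright phase clipped to the ROI dilated by the contour band, which
swallows mm-scale jitter, and on hard-contrast phantoms segmentation is
threshold-exact — repeats would agree perfectly. The emulation
therefore perturbs what a repeated measurement actually changes:
the raster grid is shifted by a seeded sub-pixel offset
(σ = 0.5 mm; same anatomy, new pixel sampling), the compacted border is
re-placed (σ = 0.5 mm on the wall), and both runs carry seeded caliper
noise (σ = 0.35 mm) on the thickness pairs. This yields high but
imperfect agreement (fractal ICC ≈ 0.96–0.99, layer-ratio ICC ≈ 0.9 on
a 15-subject cohort) with near-zero bias. The σ values are stipulated,
not fitted to any reported reproducibility figures, so the emulation
demonstrates the agreement *machinery*; it does not reproduce published
between-method reproducibility orderings.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 256 px
phantoms, 10 slices; cohorts of 28 subjects per group for group
structure, 20 per group for the FD-range sweep, and 5 per group for
repeat agreement. One phantom subject analyzes end-to-end in well under
a second on one CPU, so a full cohort run takes about a minute — these
sizes give the rank tests and coverage checks ample power while keeping
the whole suite quick.

## Known limitations

* The FD of very small borders (apical slices of small hearts) is
  resolution-limited; the admissible-range guarantee holds for the
  phantom geometry, not for arbitrarily small structures.
* Thirds are partitioned over *included* slices only; with many failed
  slices the thirds drift relative to anatomy (exclusions are logged).
* The box-count regression uses all scheduled sizes; no automatic
  scaling-window selection is attempted.
* DICOM loading expects one frame per file with slice-location
  metadata; multi-frame and 4-D cines must be reduced to end-diastole
  upstream (frame 0 of a retrospectively gated cine by convention, or
  the maximal blood-pool-area frame).
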