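# Methods

This note documents the models, conventions, and design choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
numerical details a user re-running or extending the package should know.

## Angle convention

All angles are in degrees with **anterior = 0°**, increasing
counterclockwise in a right-handed (x-right, y-up) frame. Image row indices
increase downward, so every angle computed from pixel coordinates negates
the row offset (`geometry.pixel_angles_deg`). Under this convention
`np.rot90` rotates an image by **+90°**. Directional quantities (follicle
growth angles) live on [0°, 360°); axial quantities (nematic polarity axes)
live on [0°, 180°) and are averaged after angle doubling, so 179.9° and
0.1° are close, as they must be for a headless axis.

Pixel coordinates are 0-based with x = column; pixel (r, c) spans
[c, c+1) × [r, r+1) with its center at (c + 0.5, r + 0.5). Polygon ROIs are
rasterized by **pixel-center inclusion**: a pixel belongs to the ROI iff its
center lies strictly inside the polygon. An axis-aligned square with integer
corners [0,0]–[2,2] therefore covers exactly the 2×2 half-open index block —
this rule is stated once here and tested in `tests/test_io.py`.

## Hair-follicle polarity

**Segmentation.** Each channel is thresholded globally and connected
components below `min_area` (default 30 px) are dropped. The default
threshold is the **triangle method** rather than Otsu: follicle markers
occupy ~1 % of a backskin field, and Otsu's between-class criterion is
unreliable for such unbalanced histograms — on synthetic fields it
intermittently places the threshold inside the background noise mode,
flooding the segmentation with noise components, while the triangle method
(designed for strongly skewed histograms) stays on the foreground shoulder
at all densities we generate. Otsu and fixed thresholds remain selectable.
P-cadherin components are paired with the nearest Sox9 component within
`pairing_radius` (default 3× the median component equivalent radius),
greedily by distance; unpaired components are exported with
`qc_flag=unpaired`, never silently dropped.

**Classification.** For each paired follicle we compute two geometric
signatures about the P-cadherin centroid:

- *coverage*: the angular extent of Sox9 pixels, measured as occupied
  10°-bins × 10°;
- *offset ratio*: |centroid(Sox9) − centroid(P-cad)| divided by the
  follicle radius estimate (the maximum Sox9-pixel distance from the
  P-cadherin centroid).

A follicle is **unpolarized** iff coverage ≥ 300° **or** offset ratio
< 0.15 — two independent signatures of the concentric-ring phenotype, both
configurable. Otherwise it is polarized with growth angle equal to the
direction of the vector from the Sox9 centroid to the P-cadherin centroid:
Sox9 marks the posterior of a polarized follicle and P-cadherin the
anterior, so a follicle growing toward the anterior scores ≈ 0°. These
thresholds reproduce the intended phenotype dichotomy on synthetic data
(100 % at the generator's geometry) but are a documented reconstruction,
not a ported decision rule. There is no interactive hand-correction step;
its role is replaced by per-follicle QC flags (`low_area`, `unpaired`,
`ambiguous`) that a reviewer can audit from the output CSV.

**Summaries.** `pct_polarized = 100 · n_polarized / n_total` over QC-clean
calls; the circular mean and resultant are the first trigonometric moment of
the polarized angles; rose-plot bins default to 20°. With zero polarized
follicles the circular mean is reported as NaN rather than a number.

Follicle analysis expects average-intensity projections; `io.project`
provides AIP/MIP helpers but projection is the caller's responsibility.

## Per-cell nematic order

For each labelled cell, the boundary band is the set of the cell's own
pixels within `ring_width` (default 2 px — membrane signal width is
instrument-dependent and configurable) of its outline, found by binary
erosion. Each boundary pixel's angle φ is measured about the centroid of the
*full* cell mask. The polarity vector is the intensity-weighted second
circular moment Q = Σ I e^{2iφ} / Σ I, computed **per pixel, not per edge
segment**: pixel weighting is exactly testable against a brute-force sum and
makes no assumptions about edge topology. Cells touching the image border
have truncated angular sampling; they are flagged and excluded from tissue
aggregates by default.

Tissue aggregation averages the complex nematic vectors
magnitude · e^{2i·axis} over cells (so incoherent axes cancel), and reports
an axial histogram over [0°, 180°) (default 15° bins). Inputs are assumed
pre-rotated so that the anterior–posterior axis maps to 0°.

## Junction enrichment

The image (maximum-intensity projected, if a stack is supplied) is
background-corrected by subtracting the mean of the background ROI;
negative values are clipped at zero by default (togglable via
`clip_negative`) so ROI means remain interpretable as non-negative
fluorescence. JE is the ratio of the junction-ROI mean to the cell-ROI mean
on the corrected image. A cell ROI may be a **contour band** along the cell
periphery or a **filled footprint**; the expected JE differs between the
two conventions (a filled ROI dilutes the denominator with cytoplasmic
pixels), so the convention is carried through to the output. JE is
undefined (NaN + QC flag) when the corrected cell mean is non-positive.

Group comparisons use the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`; asymptotic p by default, exact selectable). The
test suite verifies the D statistic against an independently coded
exhaustive ECDF scan.

## FRAP

With background ROI *bg*, reference ROI *ref* (a non-bleached region
tracking acquisition bleaching), and bleach ROI *F*:

1. corrected_t = (F_t − bg_t) / [(ref_t − bg_t) / mean_prebleach(ref − bg)]
2. norm_t = (F_t − F_bleach) / (F_ini − F_bleach), with F_ini the mean
   corrected pre-bleach intensity and F_bleach the corrected intensity at
   the **first post-bleach frame**; t = 0 is re-based to that frame (needed
   for Y0 to mean the post-bleach intercept).
3. One-phase association Y(t) = Y0 + (Plateau − Y0)(1 − e^{−kt}) is fitted
   by bounded trust-region least squares with Y0 ∈ [−0.2, 1],
   Plateau ∈ [−0.2, 1.5], k ∈ (0, 10] s⁻¹, multi-started from k =
   ln 2 / t_half (observed half-recovery time) plus a coarse grid
   {0.01, 0.1, 1} s⁻¹; the lowest-cost solution wins.
4. immobile fraction = 1 − (Plateau − Y0)/(1 − Y0), clipped to [0, 1] with a
   QC flag when fit noise pushes it outside.

r² = 1 − SS_res/SS_tot on the fitted points; fits with r² ≤ 0.93 are
flagged (`low_r_squared`, `converged=False`) but still reported — the
threshold is a warning, not a rejection. A flat trace makes k
unidentifiable; it is special-cased to Plateau = Y0 = mean, k = NaN,
immobile fraction 1. Per condition, both estimators are produced: a fit of
the per-timepoint **averaged** trace (the headline, appropriate when
per-trace noise is large) and per-trace fits for dispersion. Averaging
requires identical time grids; resampling is out of scope, as is XY-drift
correction of the source movies (traces are assumed extracted from
drift-corrected images).

## Synthetic generators

All generators draw from a single `numpy` Generator seeded by their
parameter object; the same parameters reproduce bit-identical outputs.
Noise is **additive Gaussian on a constant background** — the simplest
model that leaves every noiseless output equal to its closed-form pixel or
sample model, which is what the exactness tests rely on.

- **Follicles**: non-overlapping centers by rejection sampling
  (center-to-center > 2 × follicle radius; a density that cannot be placed
  raises an error naming the limit). Polarized follicles are Bernoulli
  draws; growth angles are von Mises (the standard circular unimodal
  family; the dispersion family is a modelling choice, not a measured one).
  Channel 0 is a filled P-cadherin core disc; channel 1 is a Sox9 annulus —
  full ring if unpolarized, an arc of `crescent_width` (default 120°)
  centered opposite the growth direction if polarized. Foreground intensity
  defaults to 200 over background 50 with noise SD 20 (SNR ≈ 10) in the
  validation runs — nominal values, as no intensity statistics exist to
  calibrate against.
- **Cell meshes**: rasterized Voronoi regions of seed points placed on a
  **jittered hexagonal lattice** (jitter default 0.05 of the lattice
  spacing). Epithelial packings are near-isotropic, and an unmodulated mesh
  must carry essentially no shape-driven nematic signal for
  amplitude-recovery tests to be meaningful; uniform-random seeds produce
  elongated cells whose shape anisotropy alone reaches magnitudes of ~0.5.
  Membrane intensity on each cell's boundary band follows
  I(φ) = base + amplitude · cos 2(φ − axis). The emitted truth stores each
  cell's axis and its *oracle* expected magnitude (the brute-force moment of
  the noiseless band), plus a border flag — border cells are angularly
  truncated and excluded from recovery claims.
- **Cell pairs**: two adjacent rectangular footprints; outline pixels at
  membrane intensity, the shared junction band at
  enrichment_factor × membrane intensity. The emitted cell-pair ROI is the
  membrane contour **excluding** the junction band, so the oracle JE of a
  noiseless fixture equals the enrichment factor exactly; with a cell ROI
  that includes the junction the expected JE is smaller, which is why the
  ROI convention is reported with every score.
- **FRAP traces**: three pre-bleach frames, an instantaneous bleach (the
  bleach interval contributes dead time but no samples), then 60 recovery
  frames at 5-s intervals by default. Bleach ROI signal =
  background + S · D(t) · [1 pre-bleach; (1 − depth) + depth · mobile ·
  (1 − e^{−kt}) post-bleach], reference = background + S · D(t), with a
  single shared acquisition-bleach factor D(t) = e^{−rate·t} (one reference
  ROI corrects one shared decay). The clock has t = 0 at the first
  post-bleach frame, so pre-bleach frames have D > 1; the correction
  recovers the bleach-free model up to the constant pre-bleach mean of D,
  which the normalization then cancels.

### What the generators do not emulate

No point-spread function, no photon (Poisson) noise, no 3-D structure, no
drift, no segmentation errors (meshes come with perfect labels), no
follicle-stage heterogeneity. Passing recovery tests therefore demonstrates
that the *measurement definitions and their implementation* are correct and
unbiased under the stated noise model — not that the pipeline is robust to
optical blur, mis-segmentation, or structured background in real images.
Thresholds (`ring_coverage_min`, `offset_ratio_min`, ring width, r² warning
level) are exposed precisely because real data will need judgement.

## Validation scale

The standing validation (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) uses a 200-follicle backskin at 2000×2000 px,
100-cell meshes at 500×500 px, single pair fixtures, KS samples of n = 20,
and 50 FRAP traces of 63 frames — sizes chosen to give tight statistical
bounds (binomial SE on the polarized fraction ≈ 3 points; SE of the mean
immobile fraction ≈ 0.004) while a full run stays around half a minute on
one CPU. Typical results at seed 1: classification accuracy 100 %,
recovered polarized fraction equal to the realized truth (65.5 %), circular
mean −4.0° (true draw mean −3.6°), rotation shift 90.0°, nematic oracle
deviation ~10⁻¹⁶, JE 4.0 exactly, pooled immobile fraction 0.400, k
0.0197 s⁻¹.

## Known limitations

- The follicle polarized/unpolarized rule is a geometric reconstruction;
  its thresholds were set on synthetic phenotypes and may need retuning on
  real stainings with diffuse Sox9 domains.
- Nematic order is pixel-weighted; an edge-segment-weighted variant would
  weight long and short junctions differently and is not provided.
- The one-phase model cannot represent two-component recoveries or
  diffusion-dominated FRAP; such traces will fit poorly and be flagged by
  the r² warning rather than modelled.
- CSV/TIFF/JSON are the only interchange formats; no proprietary ROI
  formats are read.
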