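# Methods

This note documents the models, estimators and design choices behind
`tumormorph`, in the order the pipeline runs them. Every number quoted here
is computed by the test suite or the analysis scripts; nothing is asserted
that the code does not measure.

## Caliper volumes and cohort statistics

Tumor volume uses the standard prolate-ellipsoid approximation
`V = a·b²/2` with `a` the longest and `b` the shortest caliper diameter.
Rows recorded with `a < b` are treated as orientation slips: swapped and
flagged with a warning, never dropped, since real caliper tables contain
them. Group data are summarized as mean ± SEM (SD with the n−1 denominator
over √n); single-animal cells report SEM as undefined.

Two-sample comparisons of raw small-sample data use the exact two-sided
Mann–Whitney U test: pooled observations receive midranks, the statistic is
U = min(U₁, U₂), and the p-value is the exact fraction of all
C(n₁+n₂, n₁) group labelings with U ≤ U_obs, enumerated in full (a rational
with that denominator). For n₁+n₂ > 20 the tie-corrected normal
approximation takes over. When only printed summaries (m, SEM, n) exist,
the summary t test applies: t = (m₁−m₂)/√(SEM₁²+SEM₂²) with
Welch–Satterthwaite degrees of freedom by default; a pooled-variance
(Student) variant with df = n₁+n₂−2 is available by flag. Welch is the
default because group SEMs in this kind of data are visibly unequal and
Welch contains the pooled test as a special case. Multi-arm endpoints use
one-way ANOVA. All p-values are two-sided; no multiple-testing correction
is applied anywhere, and the test used is named in every output row.

The growth report compares each treated arm to control day by day, flags
the first day with p < 0.05 (α configurable), and adds all pairwise
final-day volume and necropsy-weight comparisons. Days with missing control
measurements are flagged in the output rather than fatal.

## Necrosis segmentation

Necrotic tissue in an H&E section is pale and nucleus-free; viable tumor is
densely nucleated. The segmenter turns those two cues into maps over the
tumor mask:

1. *nuclear density* — the indicator of nuclear-stain pixels (blue channel
   exceeding red by a margin, default 10) smoothed with a Gaussian of
   σ = 8 px, a few cell diameters;
2. *pallor* — luminance smoothed the same way.

Both maps use normalized convolution confined to the tumor mask (smooth the
masked signal and divide by the smoothed mask), so the bright background
outside the section cannot bleed a false pallor ring into the tumor rim —
with plain smoothing that artifact alone misclassifies several percent of
the rim. A tumor pixel is necrotic when density is below its Otsu threshold
*and* pallor above its own. Otsu always splits a histogram, so both
thresholds are guarded for the necrosis-free (unimodal) case: the density
threshold is capped at 0.4× its median, the luminance threshold floored at
median + 10. The raw class is cleaned by opening + closing with a disk of
radius 3 px and removal of components under 64 px. All knobs live in
`SegmentationParams`. On sections whose tumor pixels are effectively a
single color the stage returns 0 % with a `degenerate` flag instead of
guessing.

Percent necrosis itself, 100·|necrosis|/|tumor|, is formed as an exact
integer ratio and converted to float once, so identical masks give
bit-identical percentages on any platform.

Measured performance on the synthetic sections (10 seeds, radius 256,
compact pattern, true fraction 37.4 %): mean absolute error ≈ 0.9
percentage points, Dice ≥ 0.96. A necrosis-free section scores < 1 %.
Accuracy degrades gracefully toward the extremes — a 51 % compact blob
reaches the tumor border and loses a few points to the boundary halo.

## Box-counting fractal dimension

`box_count` covers the foreground bounding box with an axis-aligned grid of
ε×ε cells anchored at the box's top-left corner (ragged right/bottom cells
count like full ones — a single fixed anchor, no offset averaging) and
counts occupied cells. `fractal_dimension` fits ln N(ε) against ln ε by
unweighted OLS over a geometric ladder of scales — powers of 2 from 2 up to
min_side/4 by default, the cap keeping the fit out of the saturated
few-box regime — and reports d_f = −slope with its standard error and r².
For hierarchically constructed masks a `scale_base` option aligns the
ladder with the construction (powers of b), which removes the grid/lattice
mismatch. A fitted value outside [0, 2] (± numerical slack) raises rather
than being clipped: it signals a degenerate input.

Validation anchors, all computed in the tests: a filled 512² square gives
d_f = 2.000, a 1-px line 1.000, the level-8 Sierpinski triangle
log 3/log 2 to machine precision (the dyadic grid aligns exactly with the
construction, so the fit is perfect and stderr is 0). On Mandelbrot
percolation (base 5, 5 levels) the estimator's 20-seed mean lands within
~0.01 of the closed-form dimension 2 + ln p/ln 5 at both p = 0.702
(d = 1.780) and p = 0.462 (d = 1.520).

Pixel replication by an integer factor k maps every ε-box of the original
onto a kε-box of the upscaled mask, so counts — and hence the fitted
dimension — are invariant over the matched scale range (asserted exactly in
the tests). With the *default* ladder the scale range itself shifts, and
for a non-self-similar blob the fitted value can drift by ~0.05; this is a
property of finite-range box counting, not of the implementation.

## Zonal partition and Ki67 scoring

The partition sorts tumor pixels by Euclidean distance to the nearest
background pixel (the raster edge counts as background via a one-pixel
pad), breaking ties lexicographically by (row, column) for bit
reproducibility, and cuts the ranking at round(0.2·A) and round(0.5·A):
the pixels nearest the boundary form the outer zone (20 % of area), the
next 30 % the intermediate zone, the core the inner 50 %. Rank cutting
makes the realized fractions exact to a pixel on any shape — on a
radius-200 disk the outer fraction is 20.000 % and the outer/intermediate
interface sits at r·√0.8 as the annulus-area formula requires. Distance
rank rather than radial fraction is this package's definition of
concentric zones; it is the natural generalization to non-circular
sections. Zero-area zones are legal (fractions (1,0,0) put everything in
the outer zone).

Nucleus detection thresholds dark pixels (luminance < 150) inside the
tumor, labels connected components, and keeps those with area in
[20, 400] px. A nucleus is called Ki67-positive when red exceeds blue by a
margin (default 30) on at least half its pixels — brown DAB against blue
hematoxylin. Nuclei are assigned to the zone containing their centroid
(matching manual counting practice); centroids outside the partition go to
a reported reject bin. A zone with zero nuclei reports its percentage as
undefined — never 0 % — so empty zones cannot bias group means. On
synthetic fields the detector achieves precision/recall ≥ 0.95 (the
residual misses are touching-nucleus merges) and positivity-call accuracy
≈ 1.0, and 30-field mean zone percentages recover a (45, 30, 15) generating
profile within 2 points.

## Synthetic-data generators

The generators define the conditions every estimator is validated under.
All of them are bit-deterministic functions of their spec (seed included);
the cohort generator splits one seed into an independent child stream per
animal, so results are stable under arm reordering.

**Percolation masks.** One retained cell is subdivided b×b per level, each
child kept with probability p; supercritical specs (b²p > 1) have box
dimension log(b²p)/log b. The retention draw covers every child of the
current grid, dead or alive, making the mask a function of the seed alone.
Extinct realizations are returned as empty masks, not silently re-sampled —
reproducibility over convenience; harnesses that need survivors re-seed.
Raster side is capped at 8192.

**Sections.** A disk tumor (radius ≥ 32 px) on a bright background. The
necrosis ground truth takes the round(f·A) tumor pixels with the lowest
placement score — distance from the centroid plus smooth noise for the
compact-interior pattern, distance to the nearest of 6–10 blob centers
seeded at 62–90 % of the radius for the dispersed-peripheral pattern — so
the realized fraction is exact to one pixel and the two patterns differ
exactly as intended: the mean boundary distance of necrotic pixels is
about twice as large for compact as for dispersed at equal fraction.
Rendering uses a fixed, well-separated stain palette (hematoxylin nuclei
≈ (60,40,120), eosin matrix ≈ (240,180,190), necrosis ≈ (235,220,215), DAB
≈ (130,80,40)) with mild Gaussian pixel noise; viable tissue is seeded with
nuclei at 0.02 per px² — near-confluent packing for a carcinoma sheet at
the emulated ~1.3 µm/px scale — and nuclei keep clear of the necrosis
border so the two H&E cues stay as crisp as they are in well-stained
tissue. What the renderer does **not** emulate: stain variability and
fading, texture within cytoplasm and necrotic debris, stromal tracts,
hemorrhage, lymphocyte infiltrates, sectioning artifacts. Passing tests
therefore demonstrate correctness of the *measurement logic* under clean
staining, not robustness to real-slide variability — the segmentation
thresholds are exposed precisely because real material would need them
re-tuned (or a stain-deconvolution front end, which is out of scope).

**Ki67 fields.** Non-overlapping disk nuclei (radius 3 px, centers ≥ 7 px
apart) are dart-thrown onto the tumor at a target density (default 5 per
1000 px²) with a spatial hash grid; if the density cannot be placed within
a bounded number of attempts the generator errors rather than degrading
silently. Each nucleus is labelled positive by an independent Bernoulli
draw at its zone's rate; chi-square goodness of fit over 50 fields confirms
the labels behave as specified.

**Cohorts.** Per animal, a baseline volume is drawn near the common entry
mean and a final volume around the arm's final mean, with between-animal SD
reconstructed from printed SEM as SEM·√n (definitional). Baseline draws are
re-centred per arm so each arm's day-0 mean equals the entry mean exactly —
arms randomized from one pool of implanted tumors share their entry mean by
design, and without centring the "common starting volume" property would
only hold in ~68 % of realizations. Final-day draws stay uncentred: the
final group mean is an estimate with sampling noise, as in the real
experiment. Between the endpoints, growth is linear in the cube root of
volume (equivalent radius), the simplest trajectory consistent with
boundary-driven growth in which proliferation is confined to the tumor
surface — the same picture the zonal Ki67 profile encodes. Each day's
volume is emitted as a caliper pair with aspect ratio a/b ~ U[1.0, 1.6],
inverted so a·b²/2 reproduces the volume to machine precision. Caliper
measurement noise is available as an optional per-diameter SD and defaults
to 0 (no published value to calibrate against). Necropsy weights are drawn
the same way when an arm specifies weight targets.

Under these conditions a synthetic n=7 arm generated around a final mean of
282.0 (SEM 30.7) yields a day-22 sample mean within 3 SEM of the target in
≥ 99 % of cohorts, and the two-arm 282-vs-519 contrast reaches Mann–Whitney
significance by day 22 in ~85 % of cohorts (~79 % on the final day alone) —
the exact test at n = 6 vs 7 with a control-arm SD of 154 mm³ simply has no
more power than that.

## Numerical and formatting choices

- 0-based, row-major pixel coordinates, origin top-left, pixel as unit
  square, everywhere. Physical scale (default 1.3 µm/px) is metadata only.
- Area ratios in exact integer arithmetic; exact Mann–Whitney p as an exact
  rational before the final float.
- CSV outputs use fixed column orders and 6-significant-digit formatting;
  re-running a pipeline with the same config and seed reproduces every CSV
  byte for byte. The effective configuration is written back out
  (`config_effective.yaml`) and re-running from it reproduces the run.
- Configs are validated strictly: unknown keys are rejected before any
  stage executes.
- Problem sizes used by the validation suites — radius-256 sections,
  side-3125 percolation masks, 10–200 replicate seeds depending on the
  statistic — were chosen so each suite pins its estimator's error well
  below the tolerances quoted above.

## Known limitations

- The segmenter is built for the two-cue synthetic stain model; real H&E
  needs stain normalization/deconvolution upstream (out of scope).
- Box counting uses a single grid anchor; offset-averaging (which reduces
  small-mask variance) is not implemented.
- The zonal partition is defined by boundary-distance rank; studies that
  drew regions freehand will differ near irregular boundaries.
- The growth model interpolates each animal between two draws; it does not
  model per-day measurement error correlation, treatment-onset dynamics, or
  dropout.
- 3-D (stack) analysis, whole-slide formats and lacunarity are not
  implemented.
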