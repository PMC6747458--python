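# Methods

`gliaquant` implements, end to end, the quantification pipeline used for
retinal whole-mount fluorescence microscopy of microglia (Iba-1-like
staining) and retinal ganglion cells (Brn3a-like nuclear staining) in a
paired-eye ocular-hypertension (OHT) study design: synthetic image
generation with known ground truth, automatic cell counting, percent-area
and per-cell morphometry, and the study's nonparametric statistics.  No
animal data ship with or are required by the package; every figure the
pipeline produces is computed at run time from seeded synthetic fields.

## The counting algorithm

Cell counting follows the classic segmentation/distance-control scheme
for mosaic-arranged microglia:

1. **Projection.**  A z-stack (optical sections every 2 μm) is averaged
   per pixel into a single projection.  `max` projection is available
   but `mean` is the default.
2. **Peak normalization.**  The projection is divided by its brightest
   pixel, mapping intensities to [0, 1].  An all-zero image is an error:
   normalization is undefined.  Because a pure-noise image would also
   normalize its brightest noise pixel to 1, an absolute *noise floor*
   guard (default 0.05, pre-normalization units) short-circuits blank
   fields to a count of zero; the flag is carried in the result.
3. **Low threshold.**  Values below 0.2 (relative) are set to zero; the
   remaining values are retained verbatim — the image is *not*
   binarized.  This preserves only the most intense part of each cell,
   normally the cell body, which is what the count keys on.
4. **Segmentation.**  Connected components of the surviving support
   (8-connectivity by default, so thin diagonal processes cannot split a
   cell), each reporting its pixel count and intensity-weighted center
   of mass.  "Center of mass" on a retained-intensity image naturally
   weights by intensity; a binary centroid is not used.
5. **Distance control.**  Segment centers closer together than a minimum
   distance are considered the same cell and counted once.  Clustering
   is the transitive closure of the strict relation *d < min_distance*
   (an exact union-find on the distance graph); one representative — the
   centroid of member centers — is emitted per cluster, sorted by (y, x)
   for determinism.  Note the transitive closure means chain-shaped
   clusters can collapse points that are themselves farther apart than
   the minimum distance; that is the intended "counted only once" rule.

The minimum distance is not fixed by the protocol this emulates and is
exposed as a parameter: defaults are 12 μm for microglia (≈ one soma
diameter), 8 μm for RGC nuclei, and 4 μm for vertical-process spots.
RGC counting runs the identical chain with the nucleus-scale distance.
Vertical processes (bright spots in the OPL/OS interface plane) are
counted by the same chain at spot scale; in the original protocol these
were counted by hand.

**Percent area (Iba1-RA).**  The fraction of pixels at or above a
threshold, reported in percent together with the threshold actually
used.  The original measurement adjusted the threshold manually per
image; the package defaults to Otsu's method for a deterministic
stand-in, with an explicit numeric override.  The study driver uses a
fixed relative threshold (0.2 of the normalized image, matching the
counting chain) so that the measure is comparable across images of one
run; this is a configuration choice (`area_threshold`), not a claim
about the original protocol.

## Morphometry proxies

The source measurements were manual (hand-drawn soma contours and a
hand-drawn polygon through the distal process tips).  The package
substitutes deterministic proxies and documents them as such:

- **Soma area** — the connected region containing the detected centroid
  at ≥ 0.5 of the *cell's own* peak (full-width-half-maximum
  convention; robust to global intensity scale), times pixel area.
- **Arbor area** — the support of the cell (≥ 0.05 of its peak) is
  skeletonized; skeleton endpoints (pixels with exactly one skeleton
  neighbour) outside the soma are the automated "distal tips"; the
  convex hull of those endpoints together with the soma boundary is the
  arbor.  A convex hull contains the hand-drawn simple polygon in
  general, so hull areas are upper proxies.  A process-free cell
  degenerates to arbor = soma, and discretization can make the
  continuous hull of pixel centers a hair smaller than the pixel-counted
  soma, in which case the invariant arbor ≥ soma wins.
- **Cell isolation** — each cell is measured in a crop of about 3× the
  expected arbor diameter (`window_um`, default 120 μm); pixels nearer
  to a competing detected centroid are masked out first, emulating the
  one-cell-at-a-time manual measurement.

The eccentricity-specific field selection of the original morphometry
(different distances from the optic disc per quadrant) is
under-specified without retina dimensions; the pipeline samples a
configurable number of fields per zone instead.

## The synthetic generator

The generator emulates the *structure* of the data, not its optics — no
PSF, no multi-channel rendering, no vasculature:

- **Microglia** are placed by rejection sampling under a mosaic
  constraint (pairwise center distance ≥ spacing; default twice the
  mean arbor radius, i.e. territories tile without overlap).  An
  infeasible packing raises an error rather than silently truncating.
  Somata render as radially symmetric discs with a logistic edge whose
  half-maximum lies exactly at the soma radius — so half-peak pixel
  counting recovers the planted area πr², the calibration every
  morphometry test relies on.  Processes are tapering Gaussian ridges
  from the soma edge to each planted tip, at 0.22 → 0.08 of the cell
  peak.  Those amplitudes are deliberately below the 0.2 counting
  threshold so that thresholding isolates somata; they are far above
  the background, so the 0.05-of-peak morphometry support keeps them.
- **RGC nuclei** are dense round process-free blobs (radius ≈ 4 μm,
  spacing 12 μm); **vertical-process spots** are compact blobs smaller
  than a microglial soma.
- **Activation profiles** scale the baseline morphology
  multiplicatively: cell density, soma radius, arbor (tip) radius,
  vertical-spot density, and RGC survival.  The study this emulates
  reports effect *directions* only (figures, no numeric tables), so all
  magnitudes here are illustrative configuration: OHT-like eyes default
  to density ×1.3, soma ×1.5, arbor ×0.7, spots ×1.4, RGC ×0.75;
  saffron-treated OHT eyes attenuate toward baseline (1.15 / 1.25 /
  0.85 / 1.35 / 0.95); contralateral eyes show a mild activation with
  no RGC loss.  None of these numbers are measured values.
- **Noise** is additive Gaussian (default σ = 0.005) on a low uniform
  background (0.01), clipped at zero — the simplest model that
  exercises the normalize-then-threshold chain.  **Z-stacks** default
  to 5 sections at 2 μm; each cell is focal on one interior section
  with a triangular axial profile (1, 0.5, 0), which makes the mean
  projection meaningful.
- **Geometry.**  Every field covers 0.1502 mm² (the area of one 20×
  whole-mount field).  The default grid is 1024² pixels
  (≈ 0.379 μm/pixel); study runs use 256² (≈ 1.51 μm/pixel) on the same
  physical area, trading resolution for speed.  Planted counts per
  field are Poisson draws through the quantile transform, so a larger
  density factor can never produce a smaller planted count at a fixed
  uniform variate.
- **Determinism.**  All randomness flows through one seeded generator;
  each image of a study receives an independent child seed in a fixed
  enumeration order, so identical design + seed reproduce identical
  pixels and byte-identical CSV outputs.

Because the generator plants smooth, well-separated, noise-lite cells,
passing its recovery tests demonstrates the *correctness of the
measurement chain*, not performance on real tissue: real whole mounts
have uneven staining, overlapping arbors, autofluorescence and optical
blur that the generator deliberately omits.

## Statistics

Group summaries are mean ± SD (n−1 denominator; a single observation is
flagged and reported with SD 0).  The comparison grid mirrors the study
design: Mann–Whitney U for unpaired contrasts (naïve vs saffron-control,
naïve vs lasered, lasered vs saffron-lasered, contralateral vs
contralateral), Wilcoxon signed-rank for the paired OHT-vs-contralateral
contrast within lasered groups, and one-way ANOVA with
Bonferroni-corrected pairwise comparisons (pooled-MSE t tests ×
number of pairs, capped at 1 — the SPSS post-hoc convention) for
retinal-zone contrasts within OHT eyes.  All tests are two-sided.

Both rank tests take an exact path when the combined sample size (or
number of nonzero pairs) is ≤ 12 — tractable by enumeration and the
regime of this study's n = 6–8 groups: the null distribution is built by
dynamic programming equivalent to enumerating all label assignments /
sign patterns, and the two-sided p is min(1, 2·min(P(T ≤ t), P(T ≥ t))).
Larger samples use the tie-corrected normal approximation.  Zero paired
differences are dropped (Wilcoxon's original convention) and noted in
the result.  No multiplicity correction is applied across the many
layer × metric contrasts, mirroring the emulated analysis, which
corrected only the zone ANOVA — a documented limitation.

**Calibration.**  Exact rank tests are discrete, so their attainable
size at α = 0.05 depends on n: the two-sided exact Wilcoxon size is
4/128 ≈ 0.031 at 6 pairs, 6/128 ≈ 0.047 at 7, 10/256 ≈ 0.039 at 8.  The
null-calibration harness therefore fixes 7 pairs for the Wilcoxon and
6 vs 8 (the naïve-vs-lasered group sizes, which take the
normal-approximation path, attained size ≈ 0.043) for the Mann–Whitney;
the ANOVA F test is exact-size 0.05 under normality.  These are
consequences of discreteness at small n, stated here so the reported
rejection rates can be read correctly.

**Unit of analysis.**  Whether the emulated analysis tested per-animal
means or per-field values is not stated; the driver defaults to
per-animal means (fields of one retina are not independent) with a
config switch (`unit: field` or `both`).

## Study driver and problem sizes

`run_study` generates every image of a configured design in memory,
quantifies it, aggregates per animal (and per zone for the ANOVA), and
emits the comparison grid plus provenance (seed, config hash, package
version).  The desk-scale default is 6 animals per group, 4 fields per
retina on 256² pixels — roughly 850 images per run versus the ~550
fields *per retina pair* of the full protocol; full scale remains
reachable through the config.  The reduced single-zone configuration
used for repeated effect-direction runs is smaller still (192² pixels,
about 360 images per run — four fields per retina, enough to resolve
the saffron-attenuation contrasts against Poisson count noise).  The validation harnesses use 200 fields for exact
count recovery, 120 fields per arm for factor recovery (sized so the
Poisson sampling error of the density ratio is ≈ 4–5%), 10 000
simulations per test for null calibration, and 100 seeded runs for the
direction template.

## Known limitations

- Rendering is additive and noise is Gaussian; there is no photon
  (Poisson) noise, optical blur, or staining heterogeneity.
- The convex-hull arbor is an upper proxy for a hand-drawn tip polygon;
  planted-vs-measured comparisons therefore recover the arbor *factor*
  (ratio between arms) rather than absolute hand-polygon areas.
- Overlapping tips of neighbouring cells can, rarely, form a small
  isolated above-threshold blob and inflate a count by one; mosaic
  spacing makes this negligible at default densities and impossible in
  the separated-mosaic recovery tests.
- The meridian-scanning field layout of the whole-mount protocol is
  approximated by a zone × field grid; eccentricity-specific sampling
  is not reproduced.
- Animals are independent draws; litter, cage or operator effects have
  no synthetic counterpart, and nested (animal/eye/field) dependence is
  handled only by averaging to the chosen unit of analysis.
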