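# Methods

## Coordinate frame and the crossing count

Root systems live in a 2D plane in cm, origin at the hypocotyl/root
junction, y positive downward to match the image row convention.  An axis
is an open polyline; a root system is one primary polyline starting at the
origin plus first-order laterals attached at arclength positions along the
primary (no second-order branching: seedling-stage phenotypes and the
NLR/MLRL trait decomposition assume a primary + laterals structure).

The core primitive counts crossings of a polyline through the circle of
radius r centred at the origin: a crossing is a strict sign change of
(distance − r) along the path.  Two conventions make the count well defined
in edge cases the sign-change wording leaves open:

- **On-circle points are outside** (distance ≥ r).  A lateral whose branch
  point lies exactly on a circle and grows outward therefore contributes no
  crossing to that circle; a root *tip* ending exactly on a circle, arriving
  from inside, contributes one.
- **Tangential touches count zero**: a local distance extremum exactly at r
  is not a strict sign change.

Because distance to the origin is convex along a straight segment, each
segment crosses a circle at most twice, and evaluating the distance at every
vertex plus each segment's interior distance minimum captures every sign
change exactly.  This makes the analytic count exact (up to floating point)
rather than sampled, which is what lets it serve as the oracle for the
image-based measurement.  Equivalence with a brute-force arc-length sampler
(10⁻⁴ cm resolution) is asserted over 1,000 random tangency-free polylines
in the test suite.

The Sholl grid is linear: radii 0.5, 1.0, … cm by default (0.5 cm spacing
matches the growth scale of *B. napus* seedling roots).  `auto_end_radius`
returns the smallest grid radius strictly beyond the outermost root point,
so every automatic profile ends with a zero-count circle.

## Synthetic root systems

The generator emulates hydroponically grown *B. napus* seedlings washed and
spread flat on a scanner plate.

**Primary axis.**  A heading random walk with fixed 0.05 cm steps — far
below the 0.5 cm circle spacing, so discretisation cannot create or destroy
grid-radius crossings.  The heading angle from vertical follows an AR(1)
process: each step it shrinks by the factor (1 − gravitropism) and receives
N(0, tortuosity_sd²) noise.  Defaults: gravitropism 0.15, tortuosity_sd
0.08 rad/step.  Total length is Normal(mean, sd) per phenotype.

**Laterals.**  Count ~ Poisson, branch positions uniform over the apical
60% of the primary, lengths log-normal — the simplest non-negative families
for a count and a right-skewed length when only group means are available.
Lateral *geometry* models the plate-spreading step rather than growth:
disentangling combs laterals outward into a feather-like fan, so

- emergence angles share a per-plant, per-side base angle
  (N(0.7, 0.35²) rad off the primary) with small per-lateral jitter
  (sd 0.1 rad) — laterals on one side run roughly parallel instead of
  wandering across each other, as a disentangled root does;
- each lateral's heading then relaxes toward the local radial
  (away-from-origin) direction at 0.03 per step, with reduced heading noise
  (0.25 × the primary's tortuosity_sd; spreading straightens laterals).

This spreading model was calibrated against the printed total-intersection
scale of the phenotypes being emulated (control I_T ≈ 170 for DR, ≈ 150–165
for DS): laterals that cross circles transversally and separately are both
what a spread root looks like and what makes the counts carry information.

**Phenotype defaults** (genotype × treatment):

| group       | primary (cm) | E[NLR] | E[MLRL] (cm) |
|-------------|--------------|--------|--------------|
| DR control  | 26 ± 2       | 40     | 1.48         |
| DR stress   | 22 ± 2       | 20     | 6.19         |
| DS control  | 21 ± 2       | 40     | 1.50         |
| DS stress   | 18 ± 2       | 24     | 2.60         |

Stress halves the DR lateral count and cuts DS's by 40%; MLRL rises under
stress in both genotypes but strongly only in DR.  The absolute control
lateral count (40) is a synthetic calibration choice — only the relative
reductions are phenotype constraints.  The DS-stress MLRL of 2.6 cm encodes
a modest upward trend that leaves the expected DS total intersection count
roughly unchanged between treatments, so the two genotypes differ in
whether stress changes I_T.  Primary lengths set the expected outermost-tip
distances near 26/22/21/18 cm; these are group-level expectations, not
per-plant guarantees.  Log-normal σ is 0.45 throughout, with log-mean
chosen so the distribution mean equals the target MLRL.

**Determinism.**  Every draw flows from one `numpy` Generator seeded
explicitly; replicate seeds are derived by SHA-256 hashing of (master seed,
genotype, treatment, replicate), so any subset of a cohort is reproducible
independently of generation order.  Ground-truth traits are recorded by
measuring the freshly built polylines with the same arclength routine
`extract_traits` uses, making recorded and re-derived traits bitwise equal.

**Re-spreading** rigidly rotates each lateral about its branch point by an
independent N(0, angle_sd²) draw (default 0.15 rad) and the whole system
about the origin by one further draw.  Rigid motions preserve arclengths
and NLR exactly in exact arithmetic; numerically the rotation perturbs
lengths at ~10⁻¹⁵ relative, so trait invariance is asserted at 10⁻⁹ cm.

## Rasterization and image-based counting

Rasterization emulates a 200 dpi office scanner: pixel size 2.54/dpi cm,
each polyline drawn as 8-connected Bresenham strokes between consecutive
vertices (thickness 1 px by default; thicker strokes by morphological
dilation), origin pixel recorded.  Images larger than 20,000 px on a side
are rejected.

`count_circle_intersections` samples the circle of integer pixel radius at
0.25 px arc spacing and classifies each sample by its nearest pixel
(out-of-bounds = background).  The count is the number of maximal
contiguous foreground runs with circular wraparound; a fully-foreground
circle counts one.  Two deliberate choices:

- **Run grouping, not pixel counting**: one crossing of a root of any
  thickness counts once, matching how a human counts roots on circles.
- **0.25 px sampling** (finer than the 1 px spacing needed for ordering):
  at 1 px spacing the visited pixel ring cuts corners and is only
  8-connected, so a diagonal stroke can cross the circle without sharing a
  pixel with the ring and be missed.  At 0.25 px the ring contains every
  pixel the continuous circle passes through, making it effectively
  4-connected — a digital Jordan curve that every 8-connected crossing
  stroke must touch.

Grid radii in cm are converted to the nearest whole pixel radius
(deterministic, documented); radii below 1 px are rejected.  Thresholding
of greyscale scans is Otsu by default (dark roots on a light background;
polarity configurable) or a fixed level; no skeletonization is applied by
default, matching direct thresholded-image analysis — a skeletonize
pre-step can be applied by the caller for thick or noisy masks.

## Oracle-equivalence validation and its domain

The validation design mirrors checking automated counts against an
independent reference per biological replicate: per-replicate Pearson
correlation between image-based and exact per-circle counts, pooled through
Fisher's z-transform.  Perfectly agreeing replicates (r = 1) have infinite
z; inside the validation report they are clipped to 1 − 10⁻⁹ and reported
as exact (`fisher_z_pool` itself rejects |r| = 1).

Equivalence is a property of the counting machinery and is well defined
only where the scene is resolvable at the scanner resolution: two crossings
less than ~2 px apart rasterize to adjacent strokes and are counted once by
*any* image-based method (or by eye), and a crossing that excurses less
than half a pixel beyond a circle leaves no pixel evidence.  The validation
fixtures are therefore drawn by rejection sampling
(`sample_resolvable_system`): a sparser phenotype (12 cm primary, ~12
laterals, 1.8 cm mean lateral length) screened on its exact vector geometry
so that on its own Sholl grid no two crossings are closer than 3.5 px, every
crossing is transversal (radial speed ≥ 0.25), and no tip lies within
1.5 px of a circle.  On 100 such fixtures the image path matches the oracle
on ≈ 97% of circles with pooled r ≈ 1.  At full cohort densities (40
laterals), sub-pixel coincidences are common enough that exact agreement
drops to ≈ 82% of circles and pooled r ≈ 0.986 — an honest resolution
limit of 200 dpi scans, not a counting defect; run_validate reports it
when pointed at cohort rows.  With salt noise added to masks the image
count only gains runs, so image I_T ≥ exact I_T — the overestimation
direction expected of pixel noise.

## Statistics

Group comparisons follow the two-stage recipe: a Bartlett test of variance
homogeneity at α = 0.05 gates between the pooled-variance t-test (variances
homogeneous) and Welch's t-test.  A zero-variance group makes the Bartlett
statistic undefined; the gate then defaults to Welch.  Significance codes
are a pure function of p: `***` < 0.001, `**` < 0.01, `*` < 0.05,
`#` < 0.1.  No multiple-testing adjustment is applied across radii or trait
pairs by default (a Holm option exists but is off).  Normality is *not*
formally tested: a Bartlett test examines variances, not distribution
shape, so the package implements only the variance gate and says so.

Per-circle comparisons align profiles on a common grid by zero-padding
beyond each replicate's extent — a circle beyond the outermost tip
genuinely has zero intersections.  Radii where both groups are identical
constants (the padded tail) are reported as not applicable.  Under the
null (identically parameterized cohorts, 5 vs 5 replicates, 200 simulated
pairs) the gated t-test rejects at 4.5% of radii where roots are present
(pooled mean count ≥ 1), within three binomial standard errors of the
nominal 5%; at near-empty radii counts are point masses at zero and the
test is conservative (≈ 1%), which errs toward fewer false positives.
Calibration is therefore stated over the informative domain.

Profile PCA is column-centred but not variance-scaled: all columns share
units (counts).  Scores are correlated against the manually-defined traits
(RL, PRL, LRL, MLRL, NLR) by Pearson correlation with two-sided t-based
p-values; the PCA pools all plants across genotype × treatment.

The PEG 6000 osmotic potential uses the Michel & Kaufmann (1973)
polynomial, Ψ(bars) = −1.18·10⁻²C − 1.18·10⁻⁴C² + 2.67·10⁻⁴CT +
8.39·10⁻⁷C²T with C in g PEG per kg water (10 × the % w/w concentration)
and T in °C, divided by 10 for MPa.  At 20 °C it gives −0.022 MPa for 2.5%
and −0.058 MPa for 5% (3 decimals), the two media of the stress protocol.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study conditions — sample
sizes (5 replicates per cell, 20 plants), scan resolution, circle grid,
trait decomposition, group contrasts and their directions — but real scans
differ in ways the simulation does not model: root thickness variation and
overlaps of the root body, pixel noise and uneven illumination (only
salt-noise robustness is tested), curved or broken primaries, second-order
laterals, and the manual steps of origin setting and brightness adjustment.
Passing tests therefore demonstrate that the measurement and statistics
machinery is correct and calibrated on geometry like the study's, not that
any particular biological effect size would be recovered from new images.

## Numerical conventions and scales used

Tolerances: structural invariants (branch-point coincidence, RL identity,
rigid-motion trait preservation) at 10⁻⁹ cm; PCA identities at 10⁻⁹;
printed osmotic potentials at 3 decimals.  Problem sizes in the test suite:
1,000 random polylines for the brute-force oracle; 1,000 systems for trait
ground-truth recovery; 100 fixtures for oracle equivalence; 500 replicates
for Monte-Carlo mean checks and the I_T monotonicity property; 200 cohort
pairs for type-I calibration; 2,000 draws for the Poisson-mean check.
These sizes give standard errors comfortably below the asserted margins
while keeping the default test run around two minutes.
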