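# Methods

## Problem and scope

`anthrobench` benchmarks single-image height/weight estimation strategies
against each other on fully synthetic data.  The package does not fit body
models to photographs; it starts where such a fit ends — a neutral-pose,
watertight, triangulated body mesh in arbitrary units with eight named
landmarks (`left/right_eye_inner/outer`, `head_apex`, `foot_a/b/c`) — and
implements everything downstream: metric scaling, geometric measurement,
competing estimator channels, and the comparative statistics.

## Measurement chain

1. **Metric scaling.**  A monocular body fit has no trustworthy absolute
   scale, so the mesh is scaled by `s = IPD_mean(gender) / IPD_mesh`,
   where the pupil centres are the midpoints of the inner/outer eye-corner
   landmarks and the population means are 6.17 cm (women) and 6.40 cm
   (men), with population SDs 0.36/0.34 cm.  Scaling by a population
   average rather than the individual's true IPD is the chain's modelled
   error source: every length acquires the factor
   `IPD_true / IPD_mean`, and weight its cube.
2. **Height** is the perpendicular distance from the head-apex landmark to
   the plane through the three foot-sole landmarks, with the plane normal
   oriented toward the apex.  The perpendicular point-to-plane reading is
   the unique rotation-invariant interpretation of "distance to the foot
   plane"; a vertical-axis difference would depend on mesh orientation.
   The apex is a supplied landmark, not an argmax over vertices (an argmax
   is pose- and orientation-dependent); a max-over-vertices fallback
   exists behind `fallback_max_vertex` for meshes without a trusted apex.
3. **Weight** is the enclosed volume times 1023 kg/m³ (a whole-body
   average density corresponding to ~34% body fat; the percentage is
   documentation only and never enters a computation).  Volume is the
   divergence-theorem sum of signed tetrahedra over faces,
   `V = (1/6) Σ_f det[a_f, b_f, c_f]` — exact for watertight,
   consistently outward-oriented triangle meshes, O(#faces), and
   translation-invariant (vertices are re-centred first purely for
   floating-point conditioning).  Non-watertight input raises a topology
   error listing the offending boundary edges; the check is the textbook
   one (every undirected edge borders exactly two faces).

Units are tracked explicitly (`raw` vs `cm`); operations refuse
unit-mismatched input rather than guessing.  Geometric predicates use an
absolute epsilon of 1e-9 on IPD-normalised coordinates, which makes the
tolerance scale-free.

## Synthetic generator

**Cohort.**  Heights and weights are drawn per gender from normal
distributions with the package defaults 161.1 ± 5.3 / 176.1 ± 8.3 cm and
60.9 ± 11.4 / 78.4 ± 12.9 kg, 33 women and 25 men.  Non-positive draws are
rejection-resampled rather than truncated-and-shifted; at these parameters
the rejection probability is negligible, so the stated means are
preserved.  Gender is binary because the population constants the
generator consumes (IPD, US averages) are published in binary form.

**Design.**  Each participant contributes 8 neutral + 6 dynamic
no-reference studio poses, 1 reference-object pose, and 2 static + 3
dynamic in-the-wild poses: 812 / 58 / 290 images for the default cohort.
Enumeration is deterministic; pose classes are labels only (no rendering).

**Body mesh.**  The template is a single surface of revolution: a smooth
monotone (PCHIP) radius profile through ankle/calf/hip/waist/shoulder/neck/
head control points, lathed around the vertical axis, closed by a flat
sole disk and an apex pole.  A lathe solid is watertight by construction,
which a union of separate head/torso/limb primitives is not without
boolean surface operations.  Three constraints are met exactly at true
scale:

* apex-to-sole-plane distance equals the target height (apex and sole are
  placed analytically);
* four eye-corner vertices are snapped onto the head ring at eye level so
  the pupil midpoints are exactly one IPD apart (the head region's radii
  are never rescaled, keeping this placement independent of body girth);
* enclosed volume equals `weight / 1023 kg·m⁻³`: the radii below the head
  are multiplied by a factor found by Brent root-finding on the discrete
  signed-tetrahedron volume itself (xtol 1e-12, giving ~1e-9 relative
  volume accuracy).  Infeasible targets (e.g. 0.001 kg at 170 cm) raise a
  generation error naming the offending parameter.

Meshes are emitted in arbitrary raw units (default 1 unit = 1 m) with the
true scale recorded in `true_cm_per_unit`.  With IPD jitter and shape
jitter disabled the output is seed-independent.  Per-participant
anatomical IPD jitter (`ipd_jitter_sd`, gendered SDs by default in the
pipeline) is what gives the mesh channel realistic, explainable errors.

**Sessions.**  Raters see one set of 58 images (per setting, each
participant appears exactly once per set; the no-reference studio pool is
subsampled to 5 sets, mirroring the 290-of-812 representative subset) plus
4 catch trials, modelled as pass/fail flags — their only analytical role
is the exclusion rule.  Estimates are truth + bias + additive Gaussian
noise (a multiplicative lognormal option exists).  The response
distribution of real untrained raters is unknown; the defaults — zero
bias, 7 cm / 11 kg SDs for non-experts, 5 cm / 9 kg for experts — are
plumbing chosen to be of the order of perceptual studies, not claims about
any particular rater pool.  Catch failure and non-completion default to
rates 65/325 and 24/325; a deterministic mode flags exactly those counts
(disjointly, catch-first), reproducing the 325 − 65 − 24 = 236 session
arithmetic.  The exclusion filter is idempotent and order-invariant, and a
session that both failed a catch and did not finish counts once, in the
catch bucket, because the arithmetic above implies disjoint buckets.

## Statistics

* **Two-level aggregation.**  All formulas are per-image first: individual
  accuracy `median_j |h̃_ij − h_i|`, crowd accuracy `|median_j h̃_ij −
  h_i|`; the report statistic is the median of the per-image values across
  images.  For single-estimate channels (mesh, expert, baseline) the two
  readings coincide.  An alternative that pools all (image, rater) errors
  is exposed via `pooling="pooled"` for sensitivity analysis, without
  endorsement.  Percent errors divide by the per-image true value before
  the across-image median — the only reading well-defined per image.
* **Medians and CIs.**  Even-length medians are the midpoint of the two
  central order statistics.  CIs are percentile bootstrap (default 1000
  iterations, 95%), resampling at the image level, seed-deterministic and
  input-order-invariant.  Fewer than two images yields a degenerate CI
  with a warning.
* **Omnibus and pairwise tests.**  The Friedman test uses within-image
  ranks with average-rank ties; the p-value defaults to the chi-square
  approximation with k−1 degrees of freedom (adequate at tens of images),
  with a within-row permutation alternative (`p_method="permutation"`)
  whose small-n correctness is verified against a brute-force oracle.
  All-pairs Wilcoxon signed-rank tests are two-sided on per-image error
  differences; zeros are dropped before ranking (the classic variant);
  the exact null is used for n ≤ 25 without ties, the tie-corrected
  normal approximation otherwise.  Differences below 1e-9 are treated as
  zeros so numerically meaningless discrepancies cannot drive
  significance.  The family-wise threshold is Bonferroni: α/#pairs
  (0.05/10 = 0.005 for five groups), with a second flag at one tenth of
  that.  Missing estimates (a declining expert) are dropped pairwise, and
  the omnibus test runs on the complete-case image subset with the dropped
  count reported.
* **Closed forms.**  The median absolute error of a constant predictor
  against a normal population is the folded-normal median, solved by
  bracketed root-finding on the CDF; a finite-mixture version covers the
  pooled two-gender cohort.  These serve as independent checks on the
  simulation-based baseline numbers.

## Pipeline and reproducibility

One master seed drives every stage through
`numpy.random.SeedSequence(master).generate_state(...)` (all derived seeds
< 2³¹), so stages are individually reproducible and a re-run with the same
config writes byte-identical CSVs; the manifest records the config echo,
package version, session-filter counts, and SHA-256 of every output.  CSVs
are UTF-8, comma-separated, '.'-decimal, with mandatory headers.

Default problem sizes were chosen so a full default run (58 participants,
1160 images, 325 sessions, 1000 bootstrap iterations) completes in well
under a minute on one core, and the test suite exercises reduced cohorts
(4–11 participants, resolution-24 meshes) where full size adds nothing to
the property being checked.

## What passing tests do and do not show

The generator emulates the *statistical structure* of a photographic
study — cohort distributions, design counts, rater pools, session
filtering — not photographs.  There is no camera geometry, no pose
variation in the meshes, no shoes/hair/headwear confounds, and the mesh
channel's only error source is the IPD ruler (plus optional shape jitter),
not model-fit failure.  Round-trip recovery within 0.5% therefore
validates the measurement chain's geometry and unit handling, not the
accuracy of any real-world image-to-mesh fit; the group comparisons on
synthetic data validate the statistical machinery, not conclusions about
real experts or crowds.

## Known limitations

* The lathe template has fused legs and a stylised silhouette; it carries
  the measurable quantities (apex, sole plane, eye landmarks, volume)
  but is not anthropometrically detailed.
* Reposing a posed mesh into the neutral pose is out of scope; the
  measurement contract requires neutral-pose input.
* Per-person true IPD is never used by the measurement chain (that is the
  point of the population-ruler design), so individual-level mesh errors
  are irreducible by construction.
* The expert channel simulates 10 experts × 5 disjoint images with one
  weight-decliner; real expert heterogeneity (method, confidence) is not
  modelled.
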