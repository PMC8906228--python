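# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic cohort does and does not emulate, and the known
limitations.

## Coordinate frames and the log dialect

Tracking logs live in two concentric frames: the patient frame (S–I, L–R,
A–P at the imaging isocenter) and the robot world frame.  The world-to-
patient map is implemented with its published coefficients verbatim,

    si =  0.7081 x_rob + 0.7061 y_rob
    lr = -0.7081 x_rob + 0.7061 y_rob
    ap =  z_rob

even though 0.7081/0.7061 make it only approximately a 45° rotation; the
exact inverse of this matrix is used for the reverse map.  Axis order is
fixed (S–I, L–R, A–P) everywhere and is not configurable.

Vendor log formats are proprietary and unpublished, so the package defines
its own plain-text dialect: `# key=value` header lines (patient id, site,
fraction index, frame, stream, column names) followed by comma-separated
numeric rows, positions in mm, six decimal places on write.  Files may be
recorded in either frame (`frame=` header); parsing normalizes every
patient-frame vector through the map above.  The robot position and
commanded offset columns of `ERsiData.log` are robot-frame quantities by
definition and are stored as recorded.  Whether a vendor logs tracking
residuals in the robot or patient frame before conversion is not publicly
documented; this dialect makes the frame explicit per file instead of
guessing.  Round trips (`parse(write(b))`) are lossless at the file
precision, and rewriting a parsed bundle is byte-identical.

## Synthetic cohort

The pipeline consumes only what logs record — a sparsely imaged fiducial
trace and per-record residual streams — so the generator controls exactly
those observables rather than simulating surrogate physics.

**Breathing motion.**  Per axis, position is `amplitude * w(t)` with
`w(c) = 2 cos^4(pi c) - 1` in cycle-fraction coordinates: value +1 at each
inhale peak, a quartically flat dwell at −1 around exhale.  This reproduces
the asymmetric dwell of free breathing, which is all the downstream stages
are sensitive to (ranges and periods).  Per-cycle periods are Gaussian
(site defaults from the published per-site mean ± SD, ~3.1–5.3 s), clipped
below at 30% of the mean to keep phases monotone.  An optional linear
baseline drift (cm/min, S–I) exists and defaults to zero.  Observed
positions add isotropic Gaussian localization noise (default 0.5 mm).

**Sampling cadence.**  Radiographic localizations (`ModelPoints`): 62 per
fraction by default at a mean interval of 66 s (uniform ±50% jitter) — the
published clinical cadence (range 40–112, mean 62).  Dense streams
(markers, modeler, predictor, robot) run at 5 Hz for 240 s; that is enough
for ~60 breathing cycles of period estimation and >1000 residual samples
per fraction while keeping the full 159-fraction cohort around a second to
simulate.

**Residual injection.**  Correlation, prediction and robotic residuals are
drawn per record from per-axis normals `N(mean + shift, sd)`, with `shift`
redrawn once per fraction from `N(0, shift_sd)` — the inter-fraction
systematic component a Van Herk-type estimator should recover.  Residuals
are additive streams, not mechanistic surrogate-model outputs: the analysis
only ever reads the logged residuals, so distributional control is what
makes parameter recovery testable.  Each source carries its own `shift_sd`
(a single shared value cannot reproduce per-source pooled SDs).

**Variance split.**  The published per-site tables pool inter- and
intra-fraction variability into a single SD per axis.  When the generator
is parameterized from those tables, the pooled variance is split equally
between the fraction-level shift and the within-fraction residual
(`variance_split = 0.5`).  The equal split is the neutral choice and is
consistent with the sizable fraction-to-fraction margin SDs the clinical
analysis reports; it is a single fixed assumption, exposed as a config
knob, not fitted.

**Seeding.**  One root seed; each fraction derives a child generator from
`(root_seed, fraction_counter)`, so any fraction is reproducible in
isolation and cohorts are byte-identical under the same seed.

## Deformation workflow

Internal deformation is proxied by the target's motion range: per fraction,
k-means (k = 3, k-means++ init, 10 restarts, fixed seed, centers sorted
lexicographically for stable ties) clusters the 3-D fiducial trace; the
per-axis span (max − min) of the cluster centers estimates the per-axis
motion range.  Spans are averaged over a site's fractions (mean ± SD), the
Euclidean norm of the mean spans gives the CoM metric R (cm), and the class
rule assigns a deformation uncertainty of 1.5 mm for R < 2 cm and 2.5 mm
otherwise; the standard uncertainty is half the class value.  The published
rule leaves R = 2 cm exactly undefined; the boundary maps to the larger
class (conservative margin).  A degenerate trace (all samples identical)
returns all centers at that point.

Two caveats are deliberate:

* With three centers, the span of cluster means cannot reach the full
  peak-to-peak range: the extreme clusters sit at the means of their
  members.  On clean generator traces the recovered span is ≈ 82% of the
  true range (the exhale dwell concentrates mass at one extreme); for a
  symmetric sinusoid the theoretical factor is ≈ 79% (arcsine density).
  Consequently, when the generator is parameterized from published
  *cluster-span* values, re-estimated spans shrink by that factor again,
  and sites whose span norm sits within ~20% above the 2-cm threshold can
  re-classify downward.  The tests assert the ≥ 80% bound on generator
  traces and exact arithmetic on the norm/classification themselves.
* The published class columns are internally inconsistent: several sites
  violate the 2-cm rule in one table or disagree between tables (e.g. a
  chest-wall entry with R = 0.094 cm listed in the large class).  The
  implementation follows the rule as stated and emits a discrepancy report
  (`deformation.rule_discrepancies`) instead of imitating the
  inconsistencies.

Breathing periods are estimated on the dominant-motion axis of the dense
model trace with peak detection (prominence 30% of the axis range, ≥ 1 s
separation, ≥ 3 peaks required); successive peak intervals give mean ± SD.

## Error statistics and the budget

For a logged source on one axis, fraction *i* yields a mean shift `<X>_i`
and SD `sigma_i` (N−1 divisor, ≥ 2 samples required).  Cohort level:

* random SD `sigma = sqrt(mean_i sigma_i^2)`;
* systematic SD `Sigma = sqrt(sum_i <X>_i^2 / (N−1))` — the uncentered RMS
  with N−1 divisor, exactly as the source recipe prints it.  This differs
  from the conventional estimator (SD of the means about their grand mean),
  is never smaller, and equals it at zero grand mean.  The default follows
  the printed formula for fidelity; `centered=True` selects the
  conventional variant.  Both are tested for recovery of injected shifts.

Uncertainty terms assume a normal PDF with coverage factor k = 2: expanded
`U = |mu| + 2 sigma`, standard `U/2`.

The five-source budget takes correlation/prediction from the logs;
segmentation (0.38 ± 0.54 mm) and targeting (0.5 ± 0.3 mm) as isotropic
constants; deformation as its class value (expanded U equal to the class,
systematic SD equal to half of it, zero random part).  Per-record robotic
residuals are summarized descriptively but excluded from margins by
default: delivery errors at individual beam nodes largely cancel over a
treatment, so the targeting term enters through the end-to-end constant
only.  All constants are overridable in configuration.  One published
inconsistency is surfaced rather than reproduced: the stated E2E inputs
give a targeting expanded uncertainty of |0.5| + 2·0.3 = 1.1 mm, while the
published uncertainty table prints 0.78 mm; the package computes 1.1 by
default and offers `targeting_expanded_mm` as an override.

## Margins

Extended Van Herk recipe (defaults σρ = 6.4 mm, β = 0.84, chosen for lung
SBRT at an 80% prescription isodose):

    M = 2.5 sqrt(Σ_S² + Σ_D² + Σ_C² + Σ_P² + Σ_T²)
        + β (sqrt(σ_C² + σ_P² + σρ²) − σρ)

evaluated exactly as printed, with Σ_S = 0.54 mm (segmentation SD),
Σ_D = class/2 (0.75 or 1.25 mm), Σ_T = 0.3 mm (E2E SD) — the only per-source
SD-form values the published analysis supplies.  Uncertainty-method margin:
`sqrt(sum_s U_s²)`, i.e. twice the quadrature of the standard
uncertainties.

Cohort margins default to per-fraction computation (each fraction's margin
uses its own tracking mean/SD — `|<X>_i|` as the systematic and `sigma_i`
as the random component for Van Herk, `|<X>_i| + 2 sigma_i` for the
uncertainty method — with the constant sources fixed), reported as
mean ± SD over fractions, matching the clinical reporting convention.  A
pooled mode computes one margin from the cohort-level budget.

Two structural properties are asserted rather than assumed: the extended
margin is bounded below by its systematic term (the penumbra bracket is
nonnegative), and in the wide-penumbra limit the random term vanishes.
Across budgets spanning the published tracking-error ranges (with the equal
variance split) the two formalisms agree within 1 mm — the measured maximum
gap over the test grid is 0.82 mm — mirroring their observed statistical
equivalence on the clinical cohort.

## Sensitivity analysis

Each hypothesis (five singles, plus segmentation+deformation and
correlation+prediction; "robot" denotes the targeting term) zeroes the
source's systematic/random SDs and uncertainty terms and recomputes both
margins; the interaction level is original − recalculated.  Both margins
are concave (square-root-of-quadrature) functions of the per-source
variances, hence submodular over the source set, so pair interactions are
*superadditive*: zeroing a pair removes at least as much as the two single
effects combined.  Interaction levels are binned low / moderate / high /
very-high at 0.5 / 1.0 / 2.0 mm — thresholds the published analysis never
defines; these defaults span the deltas implied by clinical-scale budgets
and are a configuration knob.

The published analysis does not specify its F-test; since it compares two
margin samples, the package uses the two-sample variance-ratio F
(two-sided, larger variance in the numerator, critical value at the upper
α/2 quantile), significant when both F > F_c and p < α.

At published-cohort scale, zeroing the robot term moves the margin less
than zeroing the tracking pair at every site except the smallest-motion one
(retroperitoneum), whose tracking SDs (0.11–0.25 mm) sit below the fixed
0.3-mm targeting SD — there both impacts fall in the low class.  This is a
direct consequence of the published per-site statistics, not a modeling
choice.

## Problem sizes and determinism

Default analysis sizes: the full case mix (159 fractions, 14 sites), 62
model points per fraction, 5 Hz × 240 s dense streams; the complete
pipeline runs in a few seconds and is deterministic under its seed (tables
are emitted at fixed precision, so reruns are byte-identical).  Stochastic
recovery tests use replicate cohorts at the clinical cadence (e.g. 20 × 30
fractions × 62 samples) and compare replicate-averaged estimates, so
verdicts do not hinge on a single draw.

## Known limitations

* Breathing is a single-frequency quasi-periodic waveform: no hysteresis
  loops, no physiological lung-deformation field, no imaging-mode (fiducial
  vs fiducial-free) differences.  Passing tests show the pipeline's
  estimators are correct on data matching its distributional assumptions,
  not that clinical traces satisfy them.
* Robotic per-record residuals are configurable normals; no generative
  story links them to beam-node geometry.
* The clinical per-patient margin tables cannot be reproduced without the
  original dataset; cohort-level checks are tolerance-based (the simulated
  upper-lobe S–I uncertainty-method margin lands within 0.5 mm of the
  published value).
* Segmentation and targeting errors are program-level constants, not
  estimated from images or E2E runs.
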