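# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `xorvision`.

## Stimulus family and tasks

Each stimulus is a white figure on a black canvas of 61.92° × 69.98° of
visual angle: a central vertical arm (17.06° wide, full height) plus one
horizontal arm per side placed either near the top or the bottom edge.
Several of the figure's proportions are not constrained by the design and
are package conventions, all configurable in `StimulusGeometry`:

* horizontal arm thickness = central arm width (17.06°);
* horizontal arms run from the central arm's edge to the lateral canvas
  edge and sit flush with the top/bottom edge (`arm_vertical_offset = 0`);
* raster resolution 2 px/degree (140 × 124 px), chosen to keep the V1
  model fast; distances are resolution-invariant to ≤ 0.02 at ≥ 1 px/deg;
* row-major rasters, origin top-left, 0-based indices;
* display luminance (≈124 cd/m²) is carried as metadata only.

The **linear task** labels a figure a target iff its right arm is at the
top; the **nonlinear task** iff left and right arms agree (mirror
symmetry), the XOR of the two arm-height bits. Rendering is the union of
the bars, which gives the central structural fact of the design: the
pixelwise sum of the two symmetric figures equals the pixelwise sum of the
two asymmetric ones. Class means of the nonlinear task therefore collide
*exactly* in pixel space — a sufficient condition for the failure of any
linear classifier, and the reason the perceptron cycles forever on that
task.

The manipulation operator adds or removes a single horizontal arm (the
central arm is never edited — the only convention that reproduces the
design's counts). Applied to the linear task it yields 6 unique new
positives and 6 unique new negatives; their 36 pairings contain 4 pairs of
identical stimuli, leaving 32 analysis pairs.

## V1 encoding model

`V1Encoder` implements the canonical simple-cell cascade:

1. divisive normalization of the input (each pixel divided by the local
   L2 norm over a 3 × 3 neighborhood, stabilizer 10⁻⁴);
2. convolution with a Gabor bank — 16 orientations (0°–168.75°),
   6 spatial frequencies (0.05–0.5 cycles/deg), 2 phases, valid region
   only (no padding, so edges never drive class differences);
3. output nonlinearities: threshold at 0 (half-wave rectification) and
   saturation at 1;
4. divisive normalization of each response map (3 × 3 pools), followed by
   spatial subsampling (stride 4 by default; strides 2–8 give the same
   qualitative results and are covered by tests).

Phases are paired as {0, π} — complementary on/off channels. With
rectification this pair carries the full signed Gabor response and makes
the code exactly equivariant under horizontal image flips whenever the
orientation set is symmetric about vertical, which the tests exploit.

The filter size is 31 px at 2 px/deg (≈15.5°), deliberately *narrower than
the 34 px central arm*. Every model unit, including its 3 × 3
normalization pool, then depends on at most one side of the figure. This
is V1-scale receptive-field locality, and it upgrades the empirical
observation "the model cannot solve the symmetry task" into a theorem:
for any feature that depends on only one side, the two class sums of the
2 + 2 design are equal, so class means collide in model-feature space as
well (up to FFT round-off ~10⁻⁹, far below anything a 20-epoch perceptron
can exploit). The linear task remains separable because right-side
features differ between its classes. All bank and stage constants are
exposed so the conclusion can be checked across settings; none of them is
fitted to neural data.

Model dissimilarity is `1 − Pearson correlation` between response
vectors; zero-variance responses raise rather than silently returning 0.

## Perceptron readout

The classic algorithm: labels ±1, bias via an appended constant feature,
zero initial weights, unit learning rate, add/subtract misclassified
examples, early stop on the first zero-update epoch. Activation exactly 0
predicts the distractor class, so the zero-initialized learner makes
errors and learns. Per-epoch accuracy is measured on the full training
set. Presentation order (fixed or seeded shuffle) can change the number
of epochs but never the converged/cycling outcome, which is asserted in
tests. `separability_certificate` returns "separable" only with a
zero-error epoch in hand, and "non-separable-by-mean-collision" only on
exact class-mean equality.

## Synthetic behavior

The simulator emulates the two training protocols:

* **rat**: daily sessions of 100 non-correction trials (session length is
  a package convention; only a wall-clock cap is inherent to the
  protocol), cap 40 sessions; after each error the same trial is
  re-presented as a correction trial until answered correctly (capped at
  25 re-presentations so near-deterministic agents terminate; correction
  trials are excluded from every analysis, so the cap affects no
  statistic); criterion: accuracy > 0.80 in each of two consecutive
  sessions.
* **human**: one continuous stream of 12-trial blocks, criterion: running
  mean of the last 20 trials > 0.80, cap 600 trials.

Blocks present each pair equally often (3× for 4 pairs) with the target
on the left in exactly half the trials; pair order and side assignment
are randomized independently. Staged designs are expressible (initial
pair → old+new intermixed → all pairs). The analysis of the introduction
session reports performance on both the old and the new pair, which
requires both to be on screen in that stage — the staged protocol
therefore intermixes them, an assumption of this package.

Decision strategies generate choices through a logistic rule on a
decision variable, with a lapse rate mixing in random choices:

* `LinearTemplateStrategy` — an internal weight image scored by
  correlation against each displayed image; error-driven delta-rule
  updates (toward the revealed target, away from the distractor). It
  acquires the linear task and provably cannot acquire XOR: the average
  update over the four mixed pairs is zero because the class means
  collide. An optional region mask restricts both reading and learning.
* `SymmetryOracleStrategy` — picks the mirror-symmetric image; the
  "humans can see symmetry" agent.
* `PixelSimilarityStrategy` — running-average target/distractor
  prototypes; collapses to chance on the symmetry task.
* `RegionExemplarStrategy` — configural learner over region-restricted
  appearances of the displayed pair; pairs identical in its region stay
  at chance exactly. Used to validate that the template analysis recovers
  the region an agent actually reads.
* `RandomStrategy` — guessing control.

Cohort defaults place learning speeds in the regimes the protocols were
designed around: human linear-template learners (rate 0.05, gain 4,
lapse 0.1) reach criterion in roughly 40–60 trials; the symmetry-reading
human agents in ~20; rat learners (rate 0.001, gain 4, lapse 0.1) in
roughly 12–20 sessions on the linear task and never on the nonlinear
task. These are fixed conventions of the generator, not fitted
quantities.

What the generator does *not* emulate: reaction times, shaping phases,
motivational drift, session-to-session variability beyond the choice
model, or any within-trial perceptual noise; passing tests therefore
validate the analysis pipeline, not claims about real rats or humans.

## Learning curves

Backward curves align subjects at the criterion point and keep a fixed
window ending there: 20 trials (humans, per-trial 0/1 averaged across
subjects) or 9 sessions (rats, per-session accuracy). Subjects without a
criterion point, or with fewer units than the window, are excluded with a
warning and counted, so every point averages the same subjects. Cohorts
in which nobody learns get a *terminal-aligned* curve (aligned at the end
of training) and a linear fit instead of the logistic model — the same
convention as reporting a flat line through a non-learning group.

The growth model is `p(x) = b + b·L/(1 + e^{−k(x−x0)})` with the baseline
fixed at `b = 0.55` (the printed form of the model; `b = 0.5` is
available). Curve positions are mapped to 1…window before fitting so the
midpoint bounds are interpretable. Fitting is bounded trust-region
nonlinear least squares (`scipy.optimize.least_squares`, `trf`,
tolerances 10⁻¹⁰, ≤10⁴ evaluations), starts (L, k, x0) = (0.5, 0.3, 10)
for humans / (0.5, 0.3, 5) for rats, bounds L ∈ [0, 1], k ∈ [−1, 1],
x0 ∈ [0, 20] / [0, 10]. The k interval is the corrected reading of a
constraint table whose lower/upper entries are printed transposed
(lower = 1, upper = −1 is impossible); the correction is configurable.
Non-convergence is reported, never silently swallowed.

Numerical facts worth knowing:

* noiseless curves are recovered to ~10⁻¹⁰ absolute (SSE ~10⁻²³), and
  perturbed starts within the bounds reach the same optimum to 10⁻³;
* with realistic subject noise (30 subjects × 60 Bernoulli trials per
  point) the asymptote L and midpoint x0 recover to well under 10 % of
  their ranges, but the rate k is information-limited: at steep k the
  transition spans a handful of trials against a per-point binomial SE of
  ≈0.09, and the median |k̂ − k| plateaus near 0.1–0.13 *even when the
  optimizer is started at the true parameters*. Roughly ten times as many
  subjects would be needed to push it under 0.07. Absolute k values from
  cohorts of this size should be read with that caveat; orderings
  (faster vs. slower cohorts) are reliable and tested.
* the printed model exceeds 1.0 for L > 0.818 at asymptote; generating
  probabilities are clipped at 1 when simulating.

## Template strategy analysis

Three fixed models — full canvas, upper field, lower field, split at the
horizontal midline (fraction configurable) — predict per-pair
performance: chance (0.5) when the pair is identical within the model's
region; otherwise 1.0 in binary mode, or 0.5 + 0.5·(fraction of in-region
pixels that differ) in graded mode. Binary mode makes the full model
degenerate on the 32-pair set (every pair differs somewhere); the
degenerate case is flagged and graded mode is the recommended default for
correlations. Predictions correlate with observed per-pair accuracies via
Pearson r (two-sided t p-value, optional seeded permutation p).

Per-pair accuracies use exact Clopper–Pearson 95 % intervals; the chance
band for n trials is the central 95 % acceptance region of Binomial(n, ½)
— the tightest interval obtainable at that trial count. Because the band
is an exact (conservative) acceptance region, a guessing agent falls
inside it slightly more than 95 % of the time per pair; requiring *all
four* pairs of a session window to fall inside simultaneously would hold
only ~(0.95)⁴ ≈ 81 % of the time by construction, so coverage statements
in tests are made per pair.

A region-restricted reader is subject to genuine information limits on
this design: the 32 pairs project onto few distinct upper-field
appearance contexts, some of which recur with opposite rewards, so even a
perfect upper-field learner stays near chance on those pairs. The
recovered correlations for such a cohort are therefore moderate in
absolute size; what is diagnostic (and asserted) is the ordering — the
matching region model correlates best and the complementary model is
indistinguishable from zero.

## Pipeline

`run_all` executes stimuli → perceptron → cohorts → strategy analysis
from a single config; every stage seeds its generator as
`CRC32(stage name) XOR seed` (kept below 2³¹), so stages re-run in
isolation reproduce the full run exactly. The summary JSON embeds the
config hash and seed; a repeated run with the same config is
byte-identical. The default demo completes in well under a minute on one
CPU; the full test suite in about half a minute.

## Limitations

* The stimulus grammar is exactly the arm family; no arbitrary polygons,
  no display-timing or luminance modeling.
* The V1 model's constants are declared conventions of the cited model
  family, not fits to neural data; conclusions are separability
  statements, not response predictions.
* No mixed-effects or hierarchical curve models; cross-cohort inferential
  statistics on real data are out of scope.
* Strategy learning dynamics are deliberately minimal (delta rule,
  prototype averaging, configural values); they are sufficient to
  reproduce the qualitative dissociations but are not fitted cognitive
  models.
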