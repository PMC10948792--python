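# Methods

## The inference models

A rating study presents stimuli under three conditions: situation-only (a
description of the eliciting situation), face-only (the facial portrayal),
and joint-cue (both). For every stimulus, raters judge each of K emotion
categories (default K = 13: amusement, anger, awe, contempt, disgust,
embarrassment, fear, happiness, interest, pride, sadness, shame, surprise)
for presence (yes/no) and, if present, intensity on a 4-point scale
(slightly, moderately, strongly, intensely). Absence is coded as intensity
0 and enters cross-rater means, so a cell mean is a frequency-weighted
intensity; dividing each stimulus row by its sum turns the mean ratings
into a probability distribution over categories. This conversion rests on
the probability-matching assumption: the distribution of ratings across
categories tracks the raters' subjective probabilities.

The single-cue tables estimate P(e|s) and P(e|f). A separate priors task —
"how likely are you to perceive [emotion] in daily life", on a 7-point
scale — yields the global prior P(e) by the same mean-and-normalize rule.
Under the lay causal theory (situations cause emotions, emotions cause
facial expressions, and the two cues are conditionally independent given
the emotion), an observer who sees both cues should hold

    P(e | s, f) ∝ P(e | s) · P(e | f) / P(e),

with the proportionality constant restored by renormalizing each stimulus
row. The flat-prior variant substitutes the uniform distribution for P(e)
and tests whether measured priors are informative. Candidate accounts of
joint-cue judgments are then the Situation-only table, the Face-only table,
and this integration table.

## Data preparation

Rating platforms cannot always undo a stray intensity click, so raters are
instructed to mark an accidental rating as "slight" intensity while
answering "absent". Cleaning therefore distinguishes:

- **accidental** (absent + intensity 1): corrected to "emotion absent" and
  retained;
- **incorrect** (absent + intensity > 1): removed trial by trial;
- **missing** (no presence or intensity response): removed trial by trial —
  the trial-level handling of missing responses is this package's choice;
  only the participant-level rule is fixed by the protocol;
- participants whose accidental + incorrect + missing trials **strictly
  exceed 10%** of their data are excluded entirely (exactly 10% is
  retained).

Missing (participant, stimulus, emotion) cells contribute nothing to a cell
mean (no imputation). A stimulus rated absent on every category by every
rater yields an undefined row; it is replaced by the uniform distribution
and flagged in `degenerate_rows` so downstream statistics stay defined
while the anomaly remains auditable. Prior probabilities are floored at
1e-6 before normalization so the integration rule's division is always
defined; on the 1–7 scale true zeros cannot arise from data, so the floor
only guards synthetic or truncated inputs.

## Group-level comparison

Each model is scored against the empirical joint-cue table over all
stimulus × emotion cells (604 × 13 = 7852 pairs at archival scale; 44 × 13
= 572 at the subset scale) by the product-moment correlation and the RMSE.
Uncertainty comes from a percentile bootstrap (default B = 10,000; the seed
is always explicit) resampling (stimulus, emotion) cells for overall fits
and whole stimuli for per-category analyses, matching the unit of
observation each analysis treats as exchangeable; resampling whole stimuli
for the overall fit is available as an option. Replicates with a constant
resampled vector are redrawn and counted.

Two models fitted to the same empirical vector are compared with the
Hotelling–Williams test for overlapping dependent correlations. Its
conventional degrees of freedom are n − 3; reports follow the n − 2
convention (both are stored, and at these sample sizes the p-values are
indistinguishable). Per emotion category, "model A beats model B" means the
95% percentile bootstrap interval of r_A − r_B across stimuli excludes
zero.

## Individual differences

A participant's joint-cue ratings are normalized per stimulus into a
single-rater probability table (stimuli with incomplete category coverage
are dropped with a warning). Correlating that table's cells with the three
*fixed* group-level model tables gives the participant's face-reliance,
situation-reliance and cue-integration estimates; the group tables are
inputs, never re-estimated from the individual-level sample, mirroring the
cross-study design the package supports. Estimates are Fisher r-to-z
transformed (clamped at |r| = 1 − 1e-7) before any second-level statistic.
Best-model classification is the argmax of the three correlations; exact
ties resolve by the documented precedence situation > integration > face,
favoring the simpler single-cue account.

Multivariate outliers among the z-transformed estimates are screened with
classical Mahalanobis distances against the chi-square quantile at
1 − alpha (default alpha = 0.001, df = number of estimate columns); a
robust-covariance variant is out of scope. Covariate associations are
two-tailed Pearson correlations with t = r·sqrt((n−2)/(1−r²)), an
(unadjusted) Fisher-z 95% interval, and Bonferroni multiplication of the
raw p by the caller-supplied family size, capped at 1.

Test–retest reliability uses the two-way, single-measure, *consistency*
intraclass correlation ICC(3,1): subjects are random rows, the two sessions
fixed columns, and a uniform session shift does not count against
reliability. F = MS_rows/MS_error with df (n − 1, n − 1) for two sessions,
a two-tailed p (2 · min of the two F tails), and the F-based confidence
interval, which can dip below zero for weak reliability. The
absolute-agreement form ICC(2,1) is exposed as an option (point estimate
only; its exact interval is not implemented). When the two sessions are
numerically identical the error mean square is floating-point residue and
is treated as exactly zero, so the ICC is exactly 1.

## The synthetic world

The generator mirrors the causal theory the models formalize. Each of
n_stimuli stimuli draws a situation-conditional emotion distribution from a
Dirichlet with concentration 0.7 (sparse, peaked rows resembling consensus
stimuli). The face-conditional distribution is a
`face_informativeness`-weighted mixture of the situation row with an
independent Dirichlet draw, renormalized: at 1 the face is perfectly
redundant, at 0 independent. A per-category `category_boost` *reduces* the
coupling for that column — in this world, face variance independent of the
situation is precisely the signal a joint-cue rater can only obtain from
the face, so a boosted category is one whose facial cue is diagnostic
beyond the situation (the happiness analog). The global prior is one
Dirichlet(5) draw, mildly informative and bounded away from zero.

Raters hold a strategy — face-reliant, situation-reliant, integrating, or a
weighted mixture of the three target tables — and respond by probability
matching: expected intensity is 4 × target probability, perturbed with
Gaussian noise of sd `noise_sd` on the 0–4 scale, clipped to [0, 4] and
rounded to the ordinal grid (presence = intensity > 0). An alternative
multinomial mode (four category draws per stimulus, counts as intensities)
models trial-wise probability-matching choices instead; the additive mode
is the default because it gives direct control over rater reliability. A
zero-noise rater reproduces its target exactly up to rounding. All
randomness flows from mandatory seeds; identical specs and seeds give
bitwise-identical records.

Retest simulation treats the rater's strategy weights and noise level as
the trait. Session-2 parameters are a `stability`-weighted blend of the
session-1 values with fresh draws (weights blended on the simplex; noise
levels blended with a permutation of the cohort's own values, preserving
the marginal distribution). At stability 1 the session-1 profiles are
reused verbatim, *including their response-noise seeds*: the idealized
perfectly stable rater gives identical sessions and ICC exactly 1, the
natural upper anchor for the recovery checks. Below 1, response noise is
always redrawn.

What the generator does **not** emulate: item-level idiosyncrasies of real
stimuli (all structure is exchangeable Dirichlet), rater drift within a
session, category confusions beyond what the target mixtures induce, and
demographic structure. Passing recovery tests therefore shows that the
pipeline's estimators recover the quantities this generative family
defines, not that real raters obey the lay theory.

## Demonstration scenarios and problem sizes

`emocue.scenarios` fixes the study-scale worlds used by the validation
suite and the reproduction script, so reported numbers always come from the
same code path a user would run:

- **Default world**: 44 stimuli × 13 emotions, concentration 0.7,
  face_informativeness 0.9 — sized to the individual-difference designs.
- **Single-cue cohorts**: 30 raters each, response noise sd 0.5; the priors
  task uses 45 raters.
- **Group comparison**: a heterogeneous 25-rater joint-cue cohort (59%
  situation-reliant, 23% integrating, 18% face-reliant — a predominantly
  situation-reliant population) and a face-only cohort at elevated noise
  sd 1.2. The elevated face noise encodes the scenario's premise that
  isolated portrayals are rated unreliably; with faces nearly redundant
  (informativeness 0.9) and noisily rated, the integration model loses its
  edge over the situation-only model while the face-only model falls
  clearly behind — the regime was located with the package's own design
  runs and then frozen. Expected pattern: situation ≈ integration
  (Williams test non-significant in ≳ 18/20 seeded runs), face
  significantly lower in 20/20.
- **Diagnostic-category contrast**: 120 stimuli with category_boost 0.8 on
  happiness, a 40-rater *integrating* joint cohort, and all cohorts at
  baseline noise 0.5 — a diagnostic cue can only surface in judgments if
  perceivers both receive it cleanly and use it. Expected: the per-category
  bootstrap contrast favors integration over situation-only in ≳ 18/20
  runs.
- **Classification recovery**: 30 raters per pure strategy, 44 stimuli,
  noise grid {0.1, 0.5, 1.0}, 20 seeds per level.
- **Retest**: cohorts with Dirichlet(1,1,1) strategy weights and noise
  drawn uniformly from [0.3, 1.2] (stable individual differences in
  reliability), 110 participants at study scale, 60 for the paired
  stability comparisons, 200 for the null check.

These sizes keep the full validation suite under a minute of compute while
leaving every recovery margin comfortably wide.

## Numerical conventions

- Row sums of any probability table are validated to 1 ± 1e-9; worked
  examples of the integration rule hold to 1e-12.
- Correlations are clipped to [−1, 1] after computation; zero-variance
  inputs raise a `DegenerateDataError` naming the offending side rather
  than propagating NaN.
- Bootstrap chunks are capped at ~2M resampled elements so memory stays
  flat at archival scale (7852 cells × 10,000 replicates).
- Williams-test inputs with |r| = 1 are rejected (undefined variance).
- Seeds: every stochastic routine takes an explicit seed; scenario drivers
  derive child seeds via `SeedSequence` so sub-analyses are independent and
  reproducible from one integer.

## Known limitations

- The ICC(2,1) option lacks its exact confidence interval.
- The Bonferroni family size is caller-supplied, not inferred across
  scripts; reports echo it.
- Per-emotion individual-difference estimates and alternative causal
  structures (e.g., a direct situation→expression link) are out of scope.
- RMSE and correlation can order models differently (RMSE is sensitive to
  calibration, correlation only to linear association); both are reported.
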