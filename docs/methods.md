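# Methods

This note documents the statistical procedures implemented in `diagskill`,
the conventions chosen where several are defensible, what the simulator
does and does not emulate, and the problem sizes used by the test suite and
the acceptance script.

## Data model

A *test* is a set of items, each item one (image, aspect) question; the
canonical study shape is 10 images × 8 aspects = 80 items rated by 15
panelists in up to two sessions. Responses are categorical, drawn from
closed per-aspect vocabularies of 4–6 tokens. Two conventions matter
downstream:

* `not_applicable` (and `unevaluable` for body size) are **vocabulary
  members**: a rater may positively judge that a finding cannot be
  assessed. A *missing* response is the absence of a record and is a
  different thing — it scores as incorrect and contributes nothing to
  agreement counts.
* Multi-answer accepted sets are first-class: a tied plurality vote
  produces a key entry such as {light_red, purple}, and any member counts
  as correct at scoring time.

Vocabulary membership is enforced when a file is read or a matrix is
constructed, so no analysis can observe an out-of-vocabulary category.

## Scoring and deviation values

Each of the n items is worth 100/n points (1.25 for n = 80); scores keep
full precision and are rounded only for display. Deviation values follow
the Japanese *hensachi* convention, `dv = 50 + 10 (x − x̄)/s` with the
sample (n−1) standard deviation, so the group mean maps to 50 and one sd to
10 points. A zero-sd group is degenerate; all values are then defined as 50
and a warning is emitted rather than an error, since the scores themselves
remain valid.

## Consensus keys

The consensus answer for an item is the set of categories attaining the
maximum vote count — plurality with no quorum threshold, which is the only
rule that behaves consistently across 4–6 categories where an absolute
majority often does not exist. Ties widen the accepted set rather than
being broken arbitrarily.

Two keys are compared item-by-item; "changed" defaults to set inequality,
which counts both replacement and tie widening/narrowing. A `disjoint`
definition (no shared category) is available for the stricter reading; the
choice is exposed because published reports rarely define "changed"
formally.

## Item analysis

Difficulty is the proportion correct over all examinees; bins are
lower-inclusive: easy at p ≥ 0.85, moderate on [0.50, 0.85), hard below.

The discrimination index is the fourfold-point (φ) coefficient on the top
and bottom 25 % of the total-score ranking:

    φ = (AD − BC) / √((A+B)(C+D)(A+C)(B+D)).

The square root over the full denominator product is essential — it makes φ
the Pearson correlation of the group-membership and correctness indicators,
bounded in [−1, 1]; published magnitudes for this statistic (0.3 as the
"good" threshold) are only meaningful for the rooted form. When any
marginal total is zero (for example, both extreme groups answered the item
identically) the coefficient is undefined and the item is binned
*undecidable*; this zero-denominator criterion is the exact mathematical
superset of the verbal "both groups answered the same" description.

Group size is `round_half_up(0.25 n)` by default (15 examinees → groups of
4), with `floor` and `ceil` variants because the rounding rule is rarely
stated in published work. Ties at the cut are resolved by one stable sort
on (score, examinee id): the bottom group is the first k entries, the top
group the last k, which is deterministic and guarantees disjoint groups
whenever 2k ≤ n.

## Intrarater match

The test–retest match rate for a rater is the fraction of items answered
in both sessions that received the identical category; correctness plays
no role. Per-aspect rates average the per-rater aspect-level proportions;
the overall mean and sample sd are taken across raters. Raters with no
overlapping items are omitted with a warning.

## Gwet's AC1

For item i let r_iq be the number of raters assigning category q and
r_i = Σ_q r_iq. The implementation computes

* p_a = mean over items with r_i ≥ 2 of Σ_q r_iq(r_iq−1) / (r_i(r_i−1)),
* π_q = mean over items (r_i ≥ 1) of r_iq / r_i,
* p_e = (1/(Q−1)) Σ_q π_q(1−π_q),
* AC1 = (p_a − p_e)/(1 − p_e).

Missing ratings are handled naturally: an item's agreement is computed over
the raters who rated it, and singleton items still inform prevalence.

**Category space.** Q defaults to the declared aspect vocabulary —
including `not_applicable`, since raters can and do select it — because
chance agreement depends on Q and the declared space is reproducible across
panels. `categories="observed"` restricts to categories that actually
occur, for comparison with software that does so.

**Confidence intervals** are leave-one-item-out jackknife with normal
quantiles, clipped to [−1, 1]. The jackknife was chosen over a closed-form
linearized variance because it is assumption-light and directly testable by
simulation; measured coverage of the large-panel limit at 40 items ranges
from 93 % (low agreement) to 100 % (perfect agreement) against the 95 %
nominal level.

**Pooling.** A pooled "all items" coefficient across aspects with unequal
category spaces has no canonical definition. This package pools by item
weights: pooled p_a is the mean per-item agreement over all items, pooled
p_e the item-count-weighted mean of per-aspect chance agreements, each
computed within its own Q. The jackknife then runs over all pooled items.
Other software pools differently; pooled values are comparable only within
one convention.

**Interpretation bands.** The Landis–Koch verbal scale is implemented with
half-open, lower-inclusive boundaries: poor < 0 ≤ slight < 0.20 ≤ fair
< 0.40 ≤ moderate < 0.60 ≤ substantial < 0.80 ≤ almost perfect. In
particular a coefficient of exactly 0.40 reads *moderate*. Published
tables that band rounded two-decimal coefficients are consistent with this
convention; the alternative (0.40 → fair) is not used anywhere in the
package.

## Cohort comparisons

Student's pooled-variance t-test is the default for score comparisons (the
field's standard report), with Welch by flag; the chi-squared test of
independence runs without continuity correction by default (flag to
enable); Pearson correlation uses the two-sided t-approximation. All three
delegate to scipy.stats behind validated wrappers that reject degenerate
inputs (groups of one, zero margins, zero variance) with informative
errors.

## Simulator

`simulate_panel` draws, per item, a latent true category from a per-aspect
prior — uniform over the *substantive* categories by default, since "cannot
assess" is a statement about the rater, not the tongue — then each rater
reports the truth with probability `rater_accuracy` and otherwise a wrong
category from the confusion kernel: uniform over the other categories by
default, or `adjacent` with geometric decay along the ordered vocabulary
for ordinal aspects (coating thickness, tooth marks, cracks).

The second session is coupled to the first so that `session_consistency`
(c) is exactly the expected match probability while the rater's marginal
response distribution is preserved: with κ = Σ_q P(q)² the coincidence
probability of two independent draws, the session-1 response is repeated
with probability λ = (c − κ)/(1 − κ) and otherwise redrawn independently
from the same rater model, giving P(match) = λ + (1−λ)κ = c. For targets
c < κ an independent redraw alone would agree too often, so
forced-different redraws are mixed in to thin agreement down to c (at the
cost of a slightly distorted marginal — unavoidable in that regime); a
deterministic rater (accuracy 1) always repeats, since no coupling can make
a point mass disagree with itself. The coupling was verified exact to
Monte-Carlo precision at 2×10⁵ pairs.

Defaults mirror the canonical study: 10 images, all 8 aspects, 15 raters,
accuracy 0.62 (specialists averaged ≈62/100 points against the consensus
key), session consistency 0.66 (the observed mean test–retest match). With
uniform truth over Q equiprobable categories the large-panel AC1 has the
closed form

    AC1∞ = (p_a∞ − 1/Q)/(1 − 1/Q),  p_a∞ = a² + (1−a)²/(Q−1),

which the parameter-recovery tests use as the independent target.

What the simulator does **not** emulate: correlated errors between raters
(real panels share training and conventions, which raises agreement at
fixed accuracy and makes consensus keys less stable than simulated ones),
item-difficulty heterogeneity (every item of an aspect is equally hard),
rater drift between sessions, and any image-level structure — simulation is
purely at the categorical-response level. Passing calibration tests
therefore demonstrate the correctness of the estimators under the stated
model, not that real panels satisfy that model.

`simulate_cohort` draws focal-item correctness as a Bernoulli, total
scores from group-conditional normals clipped to [0, 100], and covariates
independently from their priors; defaults reproduce the shape of a
107-professional cohort (correct rate 87/107, group score means 85.3 vs
75.8, sds 8.4 vs 11.8).

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 random small panels (≤5
raters, ≤8 items, ≤4 categories) for the AC1 oracle equivalence at 1e-12;
500 random fourfold tables for the φ–Pearson identity at 1e-12; 200
replicates per accuracy level of 10-rater × 40-item panels for parameter
recovery and CI coverage; 30 replicates of 5-rater × 80-item two-session
panels (12 000 pairs) for intrarater calibration within 3 binomial standard
errors; 10 000 single-rater items for the law-of-large-numbers calibration
of the response-frequency mixture at tolerance 0.01. These sizes give
Monte-Carlo error comfortably below each test's tolerance while keeping the
default suite fast.

Floating-point conventions: AC1 and φ comparisons against oracles use
absolute tolerance 1e-12; interval endpoints are clipped to [−1, 1]; band
classification accepts a 1e-9 slack outside [−1, 1] to absorb accumulated
rounding. Sample (n−1) standard deviations are used throughout; a
single-observation sd is NaN rather than 0.

## Known limitations

* The jackknife CI is mildly conservative at high agreement and slightly
  anticonservative at very low item counts (< 10); a linearized closed-form
  variance would be a natural addition.
* The pooled AC1 convention is one of several in circulation; see above.
* No IRT modelling (2PL/3PL) and no weighted agreement coefficients
  (Cohen/Fleiss κ, AC2) are provided; φ on extreme groups and AC1 are the
  scope.
* Chi-squared comparisons collapse multi-level covariates into single 2×K
  tables; no multiple-testing adjustment is applied.
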