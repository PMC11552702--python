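# Methods

## The valuation model

The MobQoL-7D descriptive system has seven dimensions (AC, CO, PD, IN, SE,
ME, AX — the digit order of every state index) with four severity levels
each, so the state space has 4^7 = 16,384 states. The package implements the
compositional (OPUF-style) valuation pipeline, in which each respondent's
survey answers define a complete personal utility function rather than a
single observed choice:

1. **Level rescaling.** Within each dimension, level 1 (best) is fixed at
   severity 0 and level 4 (worst) at 1. The VAS positions of levels 2 and 3
   (100 = best, 0 = worst) map to severities `1 − v/100`.
2. **Weight normalisation.** Raw swing weights (the most impactful
   dimension pinned at 100 as the yardstick) are divided by their sum, so
   the seven normalised weights sum to 1.
3. **Outer product.** `w_d · s_d(ℓ)` gives 21 un-anchored coefficients plus
   seven structural zeros at level 1.
4. **Anchoring.** If the respondent prefers the worst state `4444444` over
   dead and places it at `p` on a dead(0)–full(100) VAS, the anchor is
   `A = p/100`. If they prefer dead and place *dead* at `q` on a
   worst(0)–full(100) VAS, requiring u(dead) = 0 and u(full) = 1 under an
   affine map forces `A = −q/(100 − q)` — the unique projective rescaling
   consistent with both anchors. The two branches agree (A = 0) at
   indifference. `A` is capped at −1 per respondent, before any
   aggregation; the cap engages exactly when `q > 50`.
5. **Evaluation.** `u(x) = 1 − Σ_d w_d · s_d(x_d) · (1 − A)`, so
   `u(1111111) = 1` and `u(4444444) = A` identically.

A **value set** is the arithmetic mean of the respondents' anchored
decrement matrices; 95% CIs are percentile bootstrap over respondents
(default 10,000 iterations, seeded, 2.5/97.5 percentiles). State ranking
sorts by utility descending with ties broken by ascending index string, so
tables are bit-for-bit reproducible. Published GP and MI value sets are
embedded at their printed 3-decimal precision; computed value sets are kept
at full precision with a `rounded()` presentation helper.

## Quality control

`validate_respondent` flags rather than drops: `RANGE_VIOLATION` (a VAS or
weight outside [0, 100]), `ALL_ZERO_WEIGHTS`, `NONMONOTONE_LEVELS` (level 3
rated above level 2 in some dimension), and `INVERTED_GLOBAL` (the worst
state placed beyond full health, so the implied best-state utility falls
below the worst's). The default exclusion policy removes only structural
failures (`RANGE_VIOLATION`, `ALL_ZERO_WEIGHTS`, `INVERTED_GLOBAL`);
non-monotone intermediate ratings are retained because they express a
usable, if noisy, preference. `keep-all` and `strict` policies are
available. Range checks live in the construction operations, not the record
types, so flawed survey exports can be read, flagged and excluded by policy
instead of failing at parse time.

## Between-sample comparison

The comparison battery mirrors how two valuation samples are contrasted:
level-rating and swing-weight summaries (sample SDs, ranks by descending
mean weight with canonical-order tie-break); differences in mean anchored
decrements with independent two-sample percentile-bootstrap CIs (sizes
preserved; significant iff the CI excludes 0); anchoring summaries (branch
shares, capped-anchor moments, share of pre-cap anchors below −1); the
exhaustive per-state utility-difference distribution (population SD over
the 16,384 states; quartiles by linear interpolation); and top-k/bottom-k
ranked-state tables. The difference sign convention is A minus B
throughout (GP minus MI when comparing the published sets).

## The synthetic cohort generator

The generator emulates the five survey tasks so the whole pipeline is
testable without study data:

* **VAS ratings and swing weights** are truncated normals on [0, 100]. The
  latent location is solved (Brent's method on the analytic truncated mean)
  so the *truncated* mean equals the published per-dimension mean; the
  latent scale is set to the published SD. When the target SD is near the
  maximum attainable on a bounded interval, the realised SD falls short
  (e.g. IN level-2: target SD 18.7, realised ≈ 15.7); the mean is the
  moment the analyses consume. Sampling uses the inverse-CDF transform —
  exact truncation, one uniform per draw, bit-reproducible — rather than
  rejection, which would be distribution-identical but with data-dependent
  cost.
* **Within-dimension consistency.** Level-2 and level-3 draws share a
  Gaussian copula (default correlation 0.85), keeping the calibrated
  marginals while making inverted intermediate ratings a realistic minority
  (~10% of respondents) instead of the ~80% that independent draws would
  produce.
* **Swing weights and the yardstick.** Latent weights are drawn per
  dimension; the argmax is taken as the task-2 selection and pinned to 100,
  as the instrument does. Pinning shifts the realised marginal means
  slightly above their targets; recovery tests therefore target the
  generator's own parameters.
* **Anchoring.** The branch is Bernoulli (worst-preferred probability 0.66
  GP-like, 0.72 MI-like); each branch has its own truncated-normal VAS
  position. The positions were calibrated so the capped-anchor mean
  (≈ 0.171 / 0.242) and the ≈ 6% share of pre-cap anchors below −1 are
  reproduced. Within this family the implied capped-anchor SD (~0.52) runs
  somewhat above the published 0.47 — a two-branch truncated normal with a
  17–21% beyond-cap tail cannot be made tighter — so the mean and tail
  share are the calibrated moments.
* **Own states** are categorical per dimension, calibrated so the expected
  severity score (sum of levels, range 7–28) is ≈ 9.3 (GP-like) and ≈ 16.7
  (MI-like); an optional common severity factor (Gaussian copula) can
  correlate levels across dimensions, default off.
* **Demographics** are categorical gender and age-band marginals matching
  the two samples' compositions.

Dimensions are drawn independently of one another and of the anchor. Real
respondents surely correlate weights, ratings and anchors; no published
moments pin those correlations down, so parameter-recovery tests compare
against the generator's own expectation (`expected_decrements`, a seeded
200,000-draw Monte-Carlo integral of the joint draw — the expectation of a
product of dependent quantities does not factor into a product of means).
Consequently a value set aggregated from a synthetic cohort reproduces the
generator's expectation, not the published decrement tables: the published
GP floor is 0.129 while a large synthetic GP-like cohort gives ≈ 0.17,
because the real data's joint structure (e.g. severity-weight dependence)
is not modelled. Tests that pass on synthetic data validate the pipeline's
arithmetic, determinism and statistical calibration — not the field
realism of any particular joint distribution.

## Numerical choices

* Severity score: sum of the seven levels (7–28), monotone under
  dominance; an unweighted convenience index, not a utility.
* Invariant tolerance 1e−9 absolute; oracle-equivalence checks at 1e−12.
* Bootstraps are chunked (500 resamples per chunk) to bound index-array
  memory; results are identical to a single pass for a given seed.
* Ranking tie-break: ascending lexicographic state index.
* QALYs are piecewise-constant utility × duration, no discounting (a
  discount hook would multiply segment durations; deliberately out of
  scope).
* Population norms: 95% t-intervals on group means, groups below
  `min_group_size` flagged rather than suppressed, NotStated gender/age
  rows excluded.
* CSV round-trips read floats with `float_precision="round_trip"` so
  write → read is the identity.

## Problem sizes

Default test and acceptance runs use cohorts of 500–5,000 simulated
respondents, 100–2,000 bootstrap iterations in aggregation tests (10,000 is
the production default), a 200,000-draw Monte-Carlo oracle, and 500
replications at 1,000 iterations for the null-calibration check of the
significance flags — sizes at which Monte-Carlo error is far below the
tested tolerances while the full suite runs in well under a minute of
compute for the statistical parts.

## Known limitations

* The generator's independence assumptions understate the real joint
  variability of decrements; bootstrap CI widths on synthetic cohorts are
  not calibrated to the published CI widths.
* The published value sets are embedded at 3-decimal precision, so
  recomputed state utilities can differ from printed table values by
  accumulated rounding (up to ±0.002 for near-best states, ±0.004 for
  states with seven nonzero decrements).
* Whether non-yardstick swing weights could equal or exceed 100 in the
  original instrument is unknown; inputs above 100 are treated as range
  violations.
* The quartiles of the utility-difference distribution are reported but
  their published counterparts are not asserted in tests: the published
  25th/75th percentile values are decreasing in percentile order, which is
  inconsistent with quartiles of an ascending distribution of negative
  differences, so the intended definition is ambiguous.
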