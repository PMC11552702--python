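# mobqol

Preference-based valuation and scoring for the **MobQoL-7D**, a 7-dimension,
4-level descriptive system for mobility-related quality of life. The package
builds personal utility functions from OPUF-style survey responses
(dimension swing weighting, within-dimension level rating, dead-anchoring),
aggregates them into value sets, scores all 4^7 = 16,384 health states —
including with the published general-population (GP) and mobility-impaired
(MI) value sets — compares valuation samples, computes QALYs and population
norms, and simulates realistic synthetic survey cohorts for testing and
method development.

## The model

A health state is a 7-digit index, one level per dimension in the order
AC (Accessibility), CO (Contribution), PD (Pain/Discomfort),
IN (Independence), SE (Self-Esteem), ME (Mood/Emotions), AX (Anxiety);
`1111111` is full mobility-related health, `4444444` the worst state.

Each respondent's personal utility function (PUF) is additive and
compositional:

```
u(x) = 1 − Σ_d  w_d · s_d(x_d) · (1 − A)
```

where `w` are swing weights normalised to sum to 1, `s_d(ℓ) ∈ [0, 1]` is the
rescaled severity of level `ℓ` on dimension `d` (level 1 → 0, level 4 → 1,
intermediate levels from the VAS rating), and `A` is the anchor — the
utility of `4444444` on the dead = 0 / full health = 1 scale, capped below
at −1. Respondents who prefer being dead to the worst state place *dead* at
position `q` on a worst(0)–full(100) scale, giving `A = −q/(100 − q)` before
capping. A value set is the arithmetic mean of a sample's anchored decrement
matrices `w_d · s_d · (1 − A)`, with percentile-bootstrap 95% CIs, and
scores states the same way an individual PUF does.

## Worked example

```python
from mobqol import published_value_set, score_states, utility_difference_distribution

gp = published_value_set("GP")   # general population, n = 504
mi = published_value_set("MI")   # mobility impaired,  n = 368

print(score_states(["1111111", "1112111", "4444444"], gp))
# [1.0, 0.967, 0.129]

dist = utility_difference_distribution(gp, mi)
print(round(dist["mean"], 3), round(dist["sd"], 3))
# -0.039 0.016
```

`1112111` (some problems with Independence only) loses just the IN level-2
decrement 0.033. The scale floor is 0.129 under the GP set and 0.201 under
the MI set: the general public judges severe mobility states more harshly
than people who live with impaired mobility, by about 0.04 utility on
average across the state space (and about 0.07 among the worst states) —
differences large enough to matter in QALY calculations.

The `examples/` directory has one short script per capability: scoring,
building a PUF from raw answers, simulating a cohort and aggregating it into
a value set, comparing value sets (with figures), and QALYs/population
norms. There is also a thin CLI:

```bash
mobqol simulate --profile gp --n 500 --seed 1 --out cohort.csv
mobqol build-valueset --in cohort.csv --seed 2 --out vs.json
mobqol score --value-set GP --in states.csv --out scored.csv
mobqol compare --a GP --b MI --out report/
```

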