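"""Construct one respondent's personal utility function from survey answers.

The OPUF protocol is compositional: within-dimension level ratings are
rescaled to severities, swing weights are normalised, their outer product
gives the un-anchored coefficients, and the dead-anchoring answer maps
everything onto the QALY scale (1 = full health, 0 = dead).
"""

from mobqol import (
    AnchoringResponse,
    Demographics,
    HealthState,
    LevelRatings,
    RespondentRecord,
    SwingWeights,
    build_puf,
    parse_state_index,
)
from mobqol.states import DIMENSIONS

record = RespondentRecord(
    id="demo-001",
    sample="GP",
    own_state=HealthState((1, 1, 2, 1, 1, 2, 1)),
    level_ratings=LevelRatings(
        vas_level2={c: 70.0 for c in DIMENSIONS},  # level 2 sits at 70 on the 0-100 VAS
        vas_level3={c: 30.0 for c in DIMENSIONS},
    ),
    swing_weights=SwingWeights(
        raw={"AC": 80, "CO": 60, "PD": 100, "IN": 70, "SE": 50, "ME": 65, "AX": 55},
        most_impactful="PD",  # the task-2 yardstick, pinned at 100
    ),
    # prefers the worst state over dead, placing it at 40 on dead(0)..full(100)
    anchoring=AnchoringResponse(branch="worst_preferred", vas_position=40.0),
    demographics=Demographics(gender="Female", age_band="40-49"),
)

puf = build_puf(record)
print(f"anchor (utility of 4444444): {puf.anchor:.3f}")
print(f"normalised weights: { {c: round(float(w), 3) for c, w in zip(DIMENSIONS, puf.weights)} }")
for state in ("1111111", "1112111", "3333333", "4444444"):
    print(f"utility({state}) = {puf.utility(parse_state_index(state)):.3f}")

# The level-4 decrements sum to 1 - anchor, so the worst state scores exactly
# the anchor; every other state loses only the decrements its levels incur.
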