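"""QALY arithmetic and population norms from a simulated patient cohort.

QALYs multiply time spent in a state by its utility.  Population norms are
mean utilities of respondents' own reported states by gender and age band.
"""

import pandas as pd

from mobqol import (
    SimulationConfig,
    UtilityTrajectory,
    compute_qalys,
    default_profiles,
    population_norms,
    published_value_set,
    score_states,
    simulate_respondents,
)

# two years in a moderate state, then one year back at full health
gp = published_value_set("GP")
moderate = score_states(["2222222"], gp)[0]
traj = UtilityTrajectory(((moderate, 2.0), (1.0, 1.0)))
print(f"utility(2222222) = {moderate:.3f}; QALYs over 3 years = {compute_qalys(traj):.3f}")

# norms from a simulated mobility-impaired cohort scored with the MI set
_, mi_profile = default_profiles()
records = simulate_respondents(SimulationConfig(profile=mi_profile, n=400, seed=7))
mi = published_value_set("MI")
scored = pd.DataFrame(
    {
        "gender": [r.demographics.gender for r in records],
        "age_band": [r.demographics.age_band for r in records],
        "utility": score_states([r.own_state for r in records], mi),
    }
)
norms = population_norms(scored, min_group_size=5)
print(norms.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# rows flagged small_sample have fewer respondents than min_group_size and
# should be interpreted cautiously
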