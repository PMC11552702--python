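"""Score MobQoL-7D health states with the published value sets.

A health state is a 7-digit index, one level (1-4) per dimension in the
order AC, CO, PD, IN, SE, ME, AX.  The utility scale is anchored at 1 (no
mobility problems) and 0 (dead); values below 0 would be worse than dead.
"""

from mobqol import published_value_set, score_states

states = ["1111111", "1112111", "2111111", "4444444"]
gp = published_value_set("GP")
mi = published_value_set("MI")

print(f"{'state':>9} {'GP utility':>11} {'MI utility':>11}")
for state, u_gp, u_mi in zip(states, score_states(states, gp), score_states(states, mi)):
    print(f"{state:>9} {u_gp:>11.3f} {u_mi:>11.3f}")

# The GP (general population) set values the worst state 4444444 at 0.129,
# the MI (mobility impaired) set at 0.201: people living with impaired
# mobility judge severe states less harshly than the general public does.
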