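import numpy as np
import pytest

from mobqol import (
    AnchoringResponse,
    Demographics,
    HealthState,
    LevelRatings,
    RespondentRecord,
    SimulationConfig,
    SwingWeights,
    default_profiles,
    published_value_set,
    simulate_respondents,
)
from mobqol.states import DIMENSIONS


@pytest.fixture(scope="session")
def gp_vs():
    return published_value_set("GP")


@pytest.fixture(scope="session")
def mi_vs():
    return published_value_set("MI")


def make_record(
    rid="r1",
    sample="GP",
    vas_l2=None,
    vas_l3=None,
    weights=None,
    yardstick="AC",
    branch="worst_preferred",
    anchor_vas=30.0,
    own_state="1111111",
    gender="Female",
    age_band="30-39",
):
    """A respondent record with symmetric defaults, overridable per field.

    Default: all level-2 VAS at 200/3, level-3 at 100/3 (severities 1/3 and
    2/3), all swing weights 100, anchor 0.3.
    """
    vas_l2 = vas_l2 or {c: 200.0 / 3.0 for c in DIMENSIONS}
    vas_l3 = vas_l3 or {c: 100.0 / 3.0 for c in DIMENSIONS}
    weights = weights or {c: 100.0 for c in DIMENSIONS}
    return RespondentRecord(
        id=rid,
        sample=sample,
        own_state=HealthState(tuple(int(ch) for ch in own_state)),
        level_ratings=LevelRatings(vas_level2=dict(vas_l2), vas_level3=dict(vas_l3)),
        swing_weights=SwingWeights(raw=dict(weights), most_impactful=yardstick),
        anchoring=AnchoringResponse(branch=branch, vas_position=anchor_vas),
        demographics=Demographics(gender=gender, age_band=age_band),
    )


@pytest.fixture
def uniform_record():
    return make_record()


def random_record(rng: np.random.Generator, rid: str = "rnd") -> RespondentRecord:
    """A structurally valid record with uniformly random responses."""
    yard = rng.choice(DIMENSIONS)
    weights = {c: float(rng.uniform(0, 100)) for c in DIMENSIONS}
    weights[yard] = 100.0
    branch = "worst_preferred" if rng.random() < 0.5 else "dead_preferred"
    return make_record(
        rid=rid,
        vas_l2={c: float(rng.uniform(0, 100)) for c in DIMENSIONS},
        vas_l3={c: float(rng.uniform(0, 100)) for c in DIMENSIONS},
        weights=weights,
        yardstick=yard,
        branch=branch,
        anchor_vas=float(rng.uniform(0, 100)),
        own_state="".join(str(rng.integers(1, 5)) for _ in range(7)),
    )


@pytest.fixture(scope="session")
def gp_profile():
    return default_profiles()[0]


@pytest.fixture(scope="session")
def mi_profile():
    return default_profiles()[1]


@pytest.fixture(scope="session")
def gp_sample_500(gp_profile):
    return simulate_respondents(
        SimulationConfig(profile=gp_profile, n=500, seed=42, sample_label="GP")
    )
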