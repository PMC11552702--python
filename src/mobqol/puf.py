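"""Personal utility function (PUF) construction from OPUF survey responses.

Each respondent completes five tasks: (1) their own MobQoL-7D state plus
demographics, (2) selection of the most impactful dimension, (3) swing
weighting of all dimensions against that yardstick (fixed at 100), (4) VAS
rating of the intermediate levels 2 and 3 within each dimension (100 = best
level, 0 = worst level), and (5) a dead-anchoring task for the worst state
4444444.

The PUF is a compositional additive model.  Level ratings are rescaled to
severities in [0, 1] (level 1 -> 0, level 4 -> 1); swing weights are
normalised to sum to 1; the outer product of weights and severities gives 21
un-anchored coefficients (plus the 7 structural zeros at level 1); the
anchoring response rescales them onto the QALY-style scale where full health
is 1 and dead is 0:

    utility(state) = 1 - sum_d  w_d * s_d(level_d) * (1 - anchor)

with the anchor (the utility of 4444444) capped below at -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .states import DIMENSIONS, N_DIMENSIONS, N_LEVELS, HealthState

__all__ = [
    "LevelRatings",
    "SwingWeights",
    "AnchoringResponse",
    "Demographics",
    "RespondentRecord",
    "PersonalUtilityFunction",
    "ValidationError",
    "rescale_level_ratings",
    "normalize_weights",
    "compute_anchor",
    "raw_anchor",
    "build_puf",
    "puf_utility",
    "validate_respondent",
    "QCFlag",
]

ANCHOR_CAP = -1.0

GENDERS = ("Male", "Female", "Other", "NotStated")
AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+", "NotStated")


class ValidationError(ValueError):
    """A survey response violates a structural constraint."""


def _in_range(value: float) -> bool:
    v = float(value)
    return math.isfinite(v) and 0.0 <= v <= 100.0


def _check_vas(value: float, what: str) -> float:
    v = float(value)
    if not _in_range(v):
        raise ValidationError(f"{what} must lie in [0, 100], got {value!r}")
    return v


# The response dataclasses check *structure* (dimension coverage, known
# branch, yardstick pinned at 100) but deliberately not numeric ranges:
# out-of-range survey exports must remain representable so that
# validate_respondent can flag them and the QC policy can exclude them.
# The construction operations below raise on out-of-range input instead.


@dataclass(frozen=True)
class LevelRatings:
    """VAS positions of levels 2 and 3 per dimension (100 = best level, 0 = worst).

    ``vas_level2`` and ``vas_level3`` map dimension code -> position in [0, 100].
    """

    vas_level2: Dict[str, float]
    vas_level3: Dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("vas_level2", self.vas_level2), ("vas_level3", self.vas_level3)):
            if set(table) != set(DIMENSIONS):
                raise ValidationError(f"{name} must cover exactly the dimensions {DIMENSIONS}")


@dataclass(frozen=True)
class SwingWeights:
    """Raw swing weights per dimension with the task-2 yardstick pinned at 100."""

    raw: Dict[str, float]
    most_impactful: str

    def __post_init__(self) -> None:
        if set(self.raw) != set(DIMENSIONS):
            raise ValidationError(f"swing weights must cover exactly the dimensions {DIMENSIONS}")
        if self.most_impactful not in DIMENSIONS:
            raise ValidationError(f"unknown yardstick dimension {self.most_impactful!r}")
        if self.raw[self.most_impactful] != 100.0:
            raise ValidationError(
                f"yardstick dimension {self.most_impactful} must carry raw weight 100, "
                f"got {self.raw[self.most_impactful]!r}"
            )


@dataclass(frozen=True)
class AnchoringResponse:
    """Task-5 response: preference branch and VAS position.

    ``worst_preferred``: the respondent prefers state 4444444 over being dead
    and places it at ``vas_position`` on a dead (0) .. full health (100) scale.
    ``dead_preferred``: the respondent prefers being dead and places *dead* at
    ``vas_position`` on a 4444444 (0) .. full health (100) scale.
    """

    branch: Literal["worst_preferred", "dead_preferred"]
    vas_position: float

    def __post_init__(self) -> None:
        if self.branch not in ("worst_preferred", "dead_preferred"):
            raise ValidationError(f"unknown anchoring branch {self.branch!r}")


@dataclass(frozen=True)
class Demographics:
    gender: str = "NotStated"
    age_band: str = "NotStated"
    employment: Optional[str] = None
    ethnicity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.age_band not in AGE_BANDS:
            raise ValidationError(f"age_band must be one of {AGE_BANDS}, got {self.age_band!r}")


@dataclass(frozen=True)
class RespondentRecord:
    """One participant's five-task survey responses plus demographics."""

    id: str
    sample: str  # "GP" or "MI" (free text allowed for other cohorts)
    own_state: HealthState
    level_ratings: LevelRatings
    swing_weights: SwingWeights
    anchoring: AnchoringResponse
    demographics: Demographics = field(default_factory=Demographics)


@dataclass(frozen=True)
class PersonalUtilityFunction:
    """A respondent's anchored additive utility model.

    ``decrements`` is a 7 x 4 matrix (dimensions in canonical order, columns =
    levels 1..4) of utility losses; the level-1 column is structurally zero.
    ``utility(state) = 1 - sum of the seven applicable decrements``; the
    utility of 4444444 equals ``anchor``.
    """

    anchor: float
    decrements: np.ndarray  # (7, 4)
    weights: np.ndarray  # (7,), sums to 1
    severities: np.ndarray  # (7, 4), col 0 == 0, col 3 == 1

    def utility(self, state: HealthState) -> float:
        return puf_utility(self, state)

    def utility_best(self) -> float:
        """Utility of 1111111; exactly 1 by construction."""
        return 1.0 - float(self.decrements[:, 0].sum())

    def utility_worst(self) -> float:
        """Utility of 4444444; equals the anchor up to rounding."""
        return 1.0 - float(self.decrements[:, 3].sum())


def rescale_level_ratings(ratings: LevelRatings) -> np.ndarray:
    """Rescale VAS level ratings to severities in [0, 1].

    Returns a 7 x 4 matrix with severity 0 at level 1 (best) and 1 at level 4
    (worst); intermediate levels k get ``1 - vas_levelk / 100``.
    """
    sev = np.zeros((N_DIMENSIONS, N_LEVELS))
    for i, code in enumerate(DIMENSIONS):
        sev[i, 1] = 1.0 - _check_vas(ratings.vas_level2[code], f"vas_level2[{code}]") / 100.0
        sev[i, 2] = 1.0 - _check_vas(ratings.vas_level3[code], f"vas_level3[{code}]") / 100.0
        sev[i, 3] = 1.0
    return sev


def normalize_weights(weights: SwingWeights) -> np.ndarray:
    """Normalise raw swing weights to sum to 1 (canonical dimension order)."""
    raw = np.array(
        [_check_vas(weights.raw[code], f"swing weight [{code}]") for code in DIMENSIONS]
    )
    total = raw.sum()
    if total <= 0:
        raise ValidationError("all swing weights are zero; respondent is unusable")
    return raw / total


def raw_anchor(response: AnchoringResponse) -> float:
    """The anchor utility implied by the task-5 response, before capping.

    worst_preferred at position p on the dead(0)..full(100) scale gives p/100.
    dead_preferred places dead at q on a 4444444(0)..full(100) scale; requiring
    u(dead) = 0 and u(full) = 1 under the affine map fixes u(4444444) at
    ``-q / (100 - q)``, which is unbounded below as q -> 100.
    """
    p = _check_vas(response.vas_position, "anchoring VAS position")
    if response.branch == "worst_preferred":
        return p / 100.0
    if p >= 100.0:
        return -math.inf
    return -p / (100.0 - p)


def compute_anchor(response: AnchoringResponse) -> float:
    """Anchor utility of state 4444444 in [-1, 1], capped below at -1.

    The cap engages in the dead-preferred branch exactly when the VAS
    position exceeds 50 (position 50 gives exactly -1).
    """
    return max(ANCHOR_CAP, raw_anchor(response))


def build_puf(record: RespondentRecord) -> PersonalUtilityFunction:
    """Construct the anchored personal utility function for one respondent.

    decrement[d, l] = weight[d] * severity[d, l] * (1 - anchor), so the seven
    level-4 decrements sum to 1 - anchor and the worst state scores exactly
    the anchor.
    """
    sev = rescale_level_ratings(record.level_ratings)
    w = normalize_weights(record.swing_weights)
    anchor = compute_anchor(record.anchoring)
    dec = w[:, None] * sev * (1.0 - anchor)
    return PersonalUtilityFunction(anchor=anchor, decrements=dec, weights=w, severities=sev)


def puf_utility(puf: PersonalUtilityFunction, state: HealthState) -> float:
    """Utility of a health state under a PUF: 1 minus the applicable decrements."""
    cols = np.array(state.levels) - 1
    return 1.0 - float(puf.decrements[np.arange(N_DIMENSIONS), cols].sum())


# --- quality-control flags ---------------------------------------------------

QCFlag = Literal[
    "RANGE_VIOLATION",
    "ALL_ZERO_WEIGHTS",
    "NONMONOTONE_LEVELS",
    "INVERTED_GLOBAL",
]


def validate_respondent(record: RespondentRecord) -> List[str]:
    """Return QC flags for a structurally parseable record; never raises.

    Flags:

    * ``RANGE_VIOLATION`` — a VAS or weight outside [0, 100] slipped past
      construction (possible for records built by bypassing the dataclasses).
    * ``ALL_ZERO_WEIGHTS`` — no dimension carries any weight; the PUF is
      undefined.
    * ``NONMONOTONE_LEVELS`` — some dimension rates level 3 above level 2
      (vas_level2 < vas_level3); flagged but retained by default.
    * ``INVERTED_GLOBAL`` — the implied utility of the best state falls below
      that of the worst state (only possible for degenerate/corrupt input);
      excluded under the default QC policy, mirroring exclusions applied for
      respondents who rated the best state worse than the worst.
    """
    flags: List[str] = []

    vals = (
        list(record.level_ratings.vas_level2.values())
        + list(record.level_ratings.vas_level3.values())
        + list(record.swing_weights.raw.values())
        + [record.anchoring.vas_position]
    )
    if any(not (0.0 <= float(v) <= 100.0) for v in vals):
        flags.append("RANGE_VIOLATION")

    raw = [record.swing_weights.raw[c] for c in DIMENSIONS]
    if sum(raw) <= 0:
        flags.append("ALL_ZERO_WEIGHTS")

    if any(
        record.level_ratings.vas_level2[c] < record.level_ratings.vas_level3[c]
        for c in DIMENSIONS
    ):
        flags.append("NONMONOTONE_LEVELS")

    # best-state utility is 1 by construction and worst-state utility is the
    # anchor; inversion (worst above best) means an implied anchor above 1,
    # which only arises when the worst state is placed beyond full health.
    if (
        record.anchoring.branch == "worst_preferred"
        and float(record.anchoring.vas_position) > 100.0
    ):
        flags.append("INVERTED_GLOBAL")

    return flags


def apply_qc_policy(
    records: Sequence[RespondentRecord], policy: str = "default"
) -> Tuple[List[RespondentRecord], Dict[str, List[str]]]:
    """Split records into (kept, flags-by-id) under an exclusion policy.

    ``default`` excludes records flagged RANGE_VIOLATION, ALL_ZERO_WEIGHTS or
    INVERTED_GLOBAL (the structural failures); ``keep-all`` retains everything;
    ``strict`` additionally excludes NONMONOTONE_LEVELS.
    """
    if policy not in ("default", "keep-all", "strict"):
        raise ValidationError(f"unknown QC policy {policy!r}")
    exclude_on = {
        "default": {"RANGE_VIOLATION", "ALL_ZERO_WEIGHTS", "INVERTED_GLOBAL"},
        "strict": {"RANGE_VIOLATION", "ALL_ZERO_WEIGHTS", "INVERTED_GLOBAL", "NONMONOTONE_LEVELS"},
        "keep-all": set(),
    }[policy]
    kept: List[RespondentRecord] = []
    all_flags: Dict[str, List[str]] = {}
    for rec in records:
        flags = validate_respondent(rec)
        if flags:
            all_flags[rec.id] = flags
        if not exclude_on.intersection(flags):
            kept.append(rec)
    return kept, all_flags
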