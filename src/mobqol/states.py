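"""The MobQoL-7D descriptive system: dimensions, health states, and the state space.

The MobQoL-7D describes mobility-related quality of life on seven dimensions
(Accessibility, Contribution, Pain/Discomfort, Independence, Self-Esteem,
Mood/Emotions, Anxiety), each with four severity levels (1 = no problems,
4 = extreme problems).  A health state is one level per dimension, written as
a 7-digit index string such as ``"1112111"``; there are 4**7 = 16,384 states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Tuple

__all__ = [
    "DIMENSIONS",
    "DIMENSION_LABELS",
    "N_DIMENSIONS",
    "N_LEVELS",
    "N_STATES",
    "HealthState",
    "parse_state_index",
    "enumerate_states",
    "severity_score",
]

#: Dimension codes in canonical digit order of the state index.
DIMENSIONS: Tuple[str, ...] = ("AC", "CO", "PD", "IN", "SE", "ME", "AX")

DIMENSION_LABELS = {
    "AC": "Accessibility",
    "CO": "Contribution",
    "PD": "Pain/Discomfort",
    "IN": "Independence",
    "SE": "Self-Esteem",
    "ME": "Mood/Emotions",
    "AX": "Anxiety",
}

N_DIMENSIONS = 7
N_LEVELS = 4
N_STATES = N_LEVELS**N_DIMENSIONS  # 16,384


class StateIndexError(ValueError):
    """Raised when a health-state index string is malformed."""


@dataclass(frozen=True, order=True)
class HealthState:
    """One MobQoL-7D health state: a level in 1..4 per dimension.

    Levels are ordered by the canonical dimension order AC, CO, PD, IN, SE,
    ME, AX, matching the digits of the 7-digit index string.
    """

    levels: Tuple[int, int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != N_DIMENSIONS:
            raise StateIndexError(
                f"health state needs {N_DIMENSIONS} levels, got {len(self.levels)}"
            )
        for pos, lvl in enumerate(self.levels, start=1):
            if not isinstance(lvl, int) or not 1 <= lvl <= N_LEVELS:
                raise StateIndexError(
                    f"level at position {pos} must be an integer in 1..{N_LEVELS}, got {lvl!r}"
                )

    @property
    def index(self) -> str:
        """The 7-digit index string, e.g. ``"1112111"``."""
        return "".join(str(v) for v in self.levels)

    def __str__(self) -> str:
        return self.index

    def level(self, dimension: str) -> int:
        """Level (1..4) on a dimension given by its two-letter code."""
        return self.levels[DIMENSIONS.index(dimension)]

    def dominates(self, other: "HealthState") -> bool:
        """True if this state is at least as good on every dimension (level-wise <=)."""
        return all(a <= b for a, b in zip(self.levels, other.levels))


def parse_state_index(index: str) -> HealthState:
    """Parse a 7-character index string like ``"1112111"`` into a :class:`HealthState`.

    Inverse of ``str(state)``.  Raises :class:`StateIndexError` naming the
    offending position for a wrong length, a non-digit, or a digit outside 1-4.
    """
    if not isinstance(index, str):
        raise StateIndexError(f"state index must be a string, got {type(index).__name__}")
    if len(index) != N_DIMENSIONS:
        raise StateIndexError(
            f"state index must have exactly {N_DIMENSIONS} characters, got {len(index)} in {index!r}"
        )
    levels = []
    for pos, ch in enumerate(index, start=1):
        if ch not in "1234":
            raise StateIndexError(
                f"character {ch!r} at position {pos} of {index!r} is not a level digit 1-4"
            )
        levels.append(int(ch))
    return HealthState(tuple(levels))


def enumerate_states() -> Iterator[HealthState]:
    """Yield all 16,384 health states once each, lexicographically by index string.

    The first state is ``1111111`` and the last is ``4444444``.
    """
    for combo in itertools.product(range(1, N_LEVELS + 1), repeat=N_DIMENSIONS):
        yield HealthState(combo)


def severity_score(state: HealthState) -> int:
    """Sum of the seven levels; ranges from 7 (no problems) to 28 (extreme on all).

    A crude overall severity index: higher means worse.  It weights all
    dimensions equally and is monotone under level-wise domination.
    """
    return sum(state.levels)
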