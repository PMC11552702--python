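"""Applying value sets to data: utilities, QALYs, and population norms."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .states import HealthState, parse_state_index
from .valueset import ValueSet, state_utility

__all__ = [
    "score_states",
    "UtilityTrajectory",
    "compute_qalys",
    "population_norms",
]


def score_states(
    states: Iterable[Union[str, HealthState]], vs: ValueSet
) -> List[float]:
    """Utility of each state under a value set, preserving input order.

    Parse failures are re-raised with the offending position for easier
    debugging of tabular input.
    """
    out: List[float] = []
    for i, s in enumerate(states):
        try:
            out.append(state_utility(vs, s))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


@dataclass(frozen=True)
class UtilityTrajectory:
    """A piecewise-constant utility path: ordered (utility, duration_years) segments."""

    segments: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(u), float(d)) for u, d in self.segments)
        for u, d in segs:
            if d < 0:
                raise ValueError(f"segment duration must be non-negative, got {d}")
            if u > 1.0:
                raise ValueError(f"utility cannot exceed 1 (full health), got {u}")
        object.__setattr__(self, "segments", segs)


def compute_qalys(trajectory: UtilityTrajectory) -> float:
    """Quality-adjusted life years: sum of utility x years over the segments.

    No discounting is applied; utilities below 0 (worse than dead) subtract
    from the total as usual in QALY arithmetic.
    """
    return float(sum(u * d for u, d in trajectory.segments))


def population_norms(
    scored: pd.DataFrame,
    min_group_size: int = 5,
    utility_col: str = "utility",
) -> pd.DataFrame:
    """Mean utilities by gender x age band with 95% t-intervals.

    ``scored`` needs columns ``gender``, ``age_band`` and ``utility_col``.
    Rows with NotStated gender or age band are excluded.  Groups smaller than
    ``min_group_size`` are retained but flagged ``small_sample`` (single-row
    groups get a degenerate zero-width interval).
    """
    required = {"gender", "age_band", utility_col}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored data is missing columns: {sorted(missing)}")
    df = scored[(scored["gender"] != "NotStated") & (scored["age_band"] != "NotStated")]

    rows = []
    for (gender, band), grp in df.groupby(["gender", "age_band"], sort=True):
        vals = grp[utility_col].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            se = float(vals.std(ddof=1)) / np.sqrt(n)
            half = float(stats.t.ppf(0.975, df=n - 1)) * se
        else:
            half = 0.0
        rows.append(
            {
                "gender": gender,
                "age_band": band,
                "mean_utility": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": n,
                "small_sample": n < min_group_size,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gender", "age_band", "mean_utility", "ci_low", "ci_high", "n", "small_sample"],
    )
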