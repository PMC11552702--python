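"""Group value sets: aggregation of personal utility functions and state scoring.

A value set is the group-level mean of the respondents' anchored decrement
matrices, presented with 95% confidence intervals.  Scoring a state subtracts
the applicable mean decrements from 1, exactly as for an individual PUF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .puf import PersonalUtilityFunction
from .states import DIMENSIONS, N_DIMENSIONS, N_LEVELS, N_STATES, HealthState, parse_state_index

__all__ = [
    "ValueSet",
    "aggregate_value_set",
    "state_utility",
    "utilities_for_states",
    "tabulate_all_states",
    "all_state_indices",
]

_BOOTSTRAP_CHUNK = 500


@dataclass(frozen=True)
class ValueSet:
    """Mean utility decrement per dimension-level with 95% CIs.

    ``decrements``/``ci_low``/``ci_high`` are 7 x 4 matrices (canonical
    dimension order x levels 1..4); the level-1 column is structurally zero.
    """

    name: str
    n_respondents: int
    decrements: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in ("decrements", "ci_low", "ci_high"):
            arr = np.asarray(getattr(self, label), dtype=float)
            if arr.shape != (N_DIMENSIONS, N_LEVELS):
                raise ValueError(f"{label} must have shape (7, 4), got {arr.shape}")
            object.__setattr__(self, label, arr)

    def utility(self, state: Union[str, HealthState]) -> float:
        return state_utility(self, state)

    # --- serialization (stable key order, plain JSON) -----------------------

    def to_dict(self) -> Dict[str, object]:
        return {
            "name": self.name,
            "n_respondents": self.n_respondents,
            "dimensions": list(DIMENSIONS),
            "decrements": {
                code: [float(v) for v in self.decrements[i]]
                for i, code in enumerate(DIMENSIONS)
            },
            "ci_low": {
                code: [float(v) for v in self.ci_low[i]] for i, code in enumerate(DIMENSIONS)
            },
            "ci_high": {
                code: [float(v) for v in self.ci_high[i]] for i, code in enumerate(DIMENSIONS)
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "ValueSet":
        dims = d.get("dimensions", list(DIMENSIONS))
        if list(dims) != list(DIMENSIONS):
            raise ValueError(f"value set dimensions {dims} do not match {DIMENSIONS}")

        def mat(key: str) -> np.ndarray:
            return np.array([d[key][code] for code in DIMENSIONS], dtype=float)

        return cls(
            name=str(d["name"]),
            n_respondents=int(d["n_respondents"]),
            decrements=mat("decrements"),
            ci_low=mat("ci_low"),
            ci_high=mat("ci_high"),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ValueSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def rounded(self, decimals: int = 3) -> "ValueSet":
        """A copy rounded for publication-style presentation."""
        return ValueSet(
            name=self.name,
            n_respondents=self.n_respondents,
            decrements=np.round(self.decrements, decimals),
            ci_low=np.round(self.ci_low, decimals),
            ci_high=np.round(self.ci_high, decimals),
            provenance={**self.provenance, "rounded_to": decimals},
        )


def aggregate_value_set(
    pufs: Sequence[PersonalUtilityFunction],
    name: str = "valueset",
    iterations: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ValueSet:
    """Aggregate anchored PUFs into a value set with bootstrap 95% CIs.

    The point estimate is the arithmetic mean of the respondents' decrement
    matrices.  CIs are percentile bootstrap over respondents (resampled with
    replacement, ``iterations`` draws, 2.5/97.5 percentiles), deterministic
    given ``seed``.
    """
    pufs = list(pufs)
    if not pufs:
        raise ValueError("cannot aggregate an empty collection of personal utility functions")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    stack = np.stack([p.decrements for p in pufs])  # (n, 7, 4)
    n = stack.shape[0]
    mean = stack.mean(axis=0)

    if rng is None:
        rng = np.random.default_rng(seed)
    boot_means = np.empty((iterations, N_DIMENSIONS, N_LEVELS))
    done = 0
    while done < iterations:  # chunked to bound the index array size
        k = min(_BOOTSTRAP_CHUNK, iterations - done)
        idx = rng.integers(0, n, size=(k, n))
        boot_means[done : done + k] = stack[idx].mean(axis=1)
        done += k
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5], axis=0)

    return ValueSet(
        name=name,
        n_respondents=n,
        decrements=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        provenance={"method": "mean decrements, percentile bootstrap",
                    "iterations": iterations, "seed": seed},
    )


def state_utility(vs: ValueSet, state: Union[str, HealthState]) -> float:
    """Utility of one state under a value set: 1 minus the mean decrements."""
    if isinstance(state, str):
        state = parse_state_index(state)
    cols = np.array(state.levels) - 1
    return 1.0 - float(vs.decrements[np.arange(N_DIMENSIONS), cols].sum())


def all_state_indices() -> List[str]:
    """All 16,384 index strings in lexicographic order."""
    return ["".join(str(v + 1) for v in combo) for combo in np.ndindex(*(4,) * N_DIMENSIONS)]


def _level_matrix() -> np.ndarray:
    """(16384, 7) matrix of 0-based levels, rows in lexicographic state order."""
    return np.array(list(np.ndindex(*(4,) * N_DIMENSIONS)), dtype=np.int64)


def utilities_for_states(vs: ValueSet, levels: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorised utilities for many states.

    ``levels`` is an (n, 7) array of 0-based levels; defaults to the full
    state space in lexicographic order.
    """
    if levels is None:
        levels = _level_matrix()
    return 1.0 - vs.decrements[np.arange(N_DIMENSIONS), levels].sum(axis=1)


def tabulate_all_states(vs: ValueSet) -> pd.DataFrame:
    """Score and rank every MobQoL-7D state under a value set.

    Returns a DataFrame with columns ``state``, ``utility``, ``rank`` sorted
    by rank (1 = best).  Ties in utility are broken by ascending lexicographic
    state index so the table is bit-for-bit reproducible.
    """
    states = all_state_indices()
    util = utilities_for_states(vs)
    df = pd.DataFrame({"state": states, "utility": util})
    df = df.sort_values(["utility", "state"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, N_STATES + 1)
    return df.reset_index(drop=True)
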