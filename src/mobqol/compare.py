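"""Between-sample comparison analyses for two valuation cohorts.

Implements the comparison battery used to contrast a general-population
sample with a patient sample: level-rating and swing-weight summaries,
bootstrap inference on mean coefficient (decrement) differences, anchoring
summaries, the distribution of per-state utility differences over the full
state space, and top/bottom ranked-state tables.  Sign convention throughout
is A minus B (conventionally GP minus MI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .puf import PersonalUtilityFunction, RespondentRecord, compute_anchor, raw_anchor
from .states import DIMENSIONS, N_DIMENSIONS, N_STATES
from .valueset import ValueSet, tabulate_all_states, utilities_for_states

__all__ = [
    "level_rating_summary",
    "dimension_weighting",
    "coefficient_differences",
    "anchoring_summary",
    "utility_difference_distribution",
    "extreme_state_table",
    "ComparisonReport",
    "compare_value_sets",
    "plot_utility_histogram",
    "plot_sorted_utilities",
]

_BOOT_CHUNK = 500


def _require_nonempty(records: Sequence, what: str) -> None:
    if len(records) == 0:
        raise ValueError(f"{what} must be non-empty")


def _decrement_stack(pufs) -> np.ndarray:
    if isinstance(pufs, np.ndarray):
        if pufs.ndim != 3 or pufs.shape[1:] != (N_DIMENSIONS, 4):
            raise ValueError(f"decrement array must have shape (n, 7, 4), got {pufs.shape}")
        return pufs
    return np.stack([p.decrements for p in pufs])


def level_rating_summary(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Mean and sample SD of the raw level-2/level-3 VAS positions per dimension.

    Levels 1 and 4 are the fixed scale anchors (100 and 0) and are reported
    as constants.
    """
    _require_nonempty(records, "sample")
    rows = []
    for code in DIMENSIONS:
        l2 = np.array([r.level_ratings.vas_level2[code] for r in records], dtype=float)
        l3 = np.array([r.level_ratings.vas_level3[code] for r in records], dtype=float)
        rows.append(
            {
                "dimension": code,
                "level1": 100.0,
                "level2_mean": l2.mean(),
                "level2_sd": l2.std(ddof=1) if len(l2) > 1 else 0.0,
                "level3_mean": l3.mean(),
                "level3_sd": l3.std(ddof=1) if len(l3) > 1 else 0.0,
                "level4": 0.0,
            }
        )
    return pd.DataFrame(rows)


def dimension_weighting(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Mean/SD raw swing weight per dimension with importance ranks.

    Rank 1 is the highest mean weight; exact ties are broken by canonical
    dimension order (AC first) so the ranking is deterministic.
    """
    _require_nonempty(records, "sample")
    rows = []
    for code in DIMENSIONS:
        w = np.array([r.swing_weights.raw[code] for r in records], dtype=float)
        rows.append(
            {
                "dimension": code,
                "weight_mean": w.mean(),
                "weight_sd": w.std(ddof=1) if len(w) > 1 else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    order = np.lexsort((np.arange(N_DIMENSIONS), -df["weight_mean"].to_numpy()))
    ranks = np.empty(N_DIMENSIONS, dtype=int)
    ranks[order] = np.arange(1, N_DIMENSIONS + 1)
    df["rank"] = ranks
    return df


def coefficient_differences(
    pufs_a: Sequence[PersonalUtilityFunction],
    pufs_b: Sequence[PersonalUtilityFunction],
    iterations: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Differences in mean anchored decrements (A minus B) with bootstrap CIs.

    For each dimension x level 2-4 the point estimate is the difference of
    sample means.  The 95% CI is a percentile bootstrap resampling each
    sample independently with replacement (sizes preserved); a difference is
    flagged significant when its CI excludes 0.

    Each sample may be a sequence of PUFs or an already-stacked (n, 7, 4)
    array of decrement matrices.
    """
    _require_nonempty(pufs_a, "sample A")
    _require_nonempty(pufs_b, "sample B")
    a = _decrement_stack(pufs_a)
    b = _decrement_stack(pufs_b)
    na, nb = a.shape[0], b.shape[0]
    diff = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    boot = np.empty((iterations, N_DIMENSIONS, 4))
    done = 0
    while done < iterations:
        k = min(_BOOT_CHUNK, iterations - done)
        ia = rng.integers(0, na, size=(k, na))
        ib = rng.integers(0, nb, size=(k, nb))
        boot[done : done + k] = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        done += k
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    rows = []
    for i, code in enumerate(DIMENSIONS):
        for lvl in (2, 3, 4):
            j = lvl - 1
            rows.append(
                {
                    "dimension": code,
                    "level": lvl,
                    "difference": diff[i, j],
                    "ci_low": lo[i, j],
                    "ci_high": hi[i, j],
                    "significant": bool(lo[i, j] > 0 or hi[i, j] < 0),
                }
            )
    return pd.DataFrame(rows)


def anchoring_summary(records: Sequence[RespondentRecord]) -> Dict[str, float]:
    """Anchoring statistics for one sample.

    Reports the count and share preferring the worst state 4444444 over being
    dead, the mean/SD of the capped anchors, and the count/share whose
    pre-cap anchor falls below -1 (i.e. dead placed above the VAS midpoint).
    """
    _require_nonempty(records, "sample")
    n = len(records)
    worst_pref = sum(1 for r in records if r.anchoring.branch == "worst_preferred")
    capped = np.array([compute_anchor(r.anchoring) for r in records])
    below = sum(1 for r in records if raw_anchor(r.anchoring) < -1.0)
    return {
        "n": n,
        "n_worst_preferred": worst_pref,
        "pct_worst_preferred": 100.0 * worst_pref / n,
        "mean_anchor": float(capped.mean()),
        "sd_anchor": float(capped.std(ddof=1)) if n > 1 else 0.0,
        "n_below_minus1": below,
        "pct_below_minus1": 100.0 * below / n,
    }


def utility_difference_distribution(vs_a: ValueSet, vs_b: ValueSet) -> Dict[str, float]:
    """Distribution of per-state utility differences (A minus B) over all 16,384 states.

    Exhaustive enumeration; the SD is the population SD over the state space
    and the quartiles use linear interpolation between order statistics.
    """
    d = utilities_for_states(vs_a) - utilities_for_states(vs_b)
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return {
        "n_states": int(d.size),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=0)),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "min": float(d.min()),
        "max": float(d.max()),
    }


def extreme_state_table(vs_a: ValueSet, vs_b: ValueSet, k: int = 25) -> pd.DataFrame:
    """Top-k and bottom-k states by sample-A rank, with both utilities and ranks.

    ``difference`` is A minus B; ``rank_difference`` is B's rank minus A's
    rank (positive when B ranks the state worse... i.e. at a larger rank
    number).  Rows are ordered by A's rank.
    """
    if not 1 <= k <= N_STATES // 2:
        raise ValueError(f"k must lie in 1..{N_STATES // 2}, got {k}")
    ta = tabulate_all_states(vs_a).set_index("state")
    tb = tabulate_all_states(vs_b).set_index("state")
    picked = pd.concat([ta.iloc[:k], ta.iloc[-k:]])
    rows = []
    for state, row in picked.iterrows():
        rb = tb.loc[state]
        rows.append(
            {
                "state": state,
                "utility_a": row["utility"],
                "utility_b": rb["utility"],
                "difference": row["utility"] - rb["utility"],
                "rank_a": int(row["rank"]),
                "rank_b": int(rb["rank"]),
                "rank_difference": int(rb["rank"]) - int(row["rank"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Bundle of the between-sample comparison tables."""

    level_ratings: Optional[pd.DataFrame] = None
    weighting: Optional[pd.DataFrame] = None
    coefficients: Optional[pd.DataFrame] = None
    anchoring: Optional[Dict[str, Dict[str, float]]] = None
    utility_difference: Optional[Dict[str, float]] = None
    extreme_states: Optional[pd.DataFrame] = None
    provenance: Dict[str, object] = field(default_factory=dict)


def compare_value_sets(vs_a: ValueSet, vs_b: ValueSet, k: int = 25) -> ComparisonReport:
    """Value-set-level comparison: difference distribution plus extreme-state table."""
    return ComparisonReport(
        utility_difference=utility_difference_distribution(vs_a, vs_b),
        extreme_states=extreme_state_table(vs_a, vs_b, k=k),
        provenance={"a": vs_a.name, "b": vs_b.name, "k": k},
    )


# --- plotting ----------------------------------------------------------------


def plot_utility_histogram(vs_a: ValueSet, vs_b: ValueSet, bins: int = 50, ax=None):
    """Overlaid histograms of the 16,384 state utilities under two value sets."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for vs, color in ((vs_a, "tab:purple"), (vs_b, "tab:olive")):
        ax.hist(utilities_for_states(vs), bins=bins, alpha=0.55, label=vs.name, color=color)
    ax.set_xlabel("utility (0 = dead, 1 = full health)")
    ax.set_ylabel("number of health states")
    ax.legend()
    return ax


def plot_sorted_utilities(vs_a: ValueSet, vs_b: ValueSet, ax=None):
    """Utility curves over all states ordered by the first value set's ranking.

    The first set's curve is monotone by construction; the second is plotted
    against the same state ordering, so its scatter shows how the two sets
    rank states differently.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ta = tabulate_all_states(vs_a)
    ub = utilities_for_states(vs_b)
    order = {s: i for i, s in enumerate(ta["state"])}
    # reorder B's utilities to A's ranking
    import numpy as _np

    idx = _np.empty(len(ta), dtype=int)
    from .valueset import all_state_indices

    for i, s in enumerate(all_state_indices()):
        idx[order[s]] = i
    x = _np.arange(len(ta), 0, -1)
    ax.plot(x, ub[idx], lw=0.5, color="tab:olive", label=vs_b.name)
    ax.plot(x, ta["utility"], lw=1.5, color="tab:purple", label=vs_a.name)
    ax.set_xlabel(f"health states, worst to best under the {vs_a.name} ranking")
    ax.set_ylabel("utility")
    ax.legend()
    return ax
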