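"""The published MobQoL-7D value sets and reference extreme-state table.

Two value sets were released with the instrument: GP, elicited from a
representative UK general-population sample (n = 504), and MI, from a
balanced sample of individuals with impaired mobility (n = 368).  Both are
mean anchored decrements per dimension-level with 95% confidence intervals,
printed to three decimals.

``EXTREME_STATE_REFERENCE`` carries the released top-25 / bottom-25 ranked
states with their published utilities and ranks under both sets; it is used
as a cross-check for recomputed utilities and as the canonical bottom-25
state list.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .states import DIMENSIONS
from .valueset import ValueSet

__all__ = ["published_value_set", "available_value_sets", "extreme_state_reference"]

# dimension code -> (level2, level3, level4); each entry (mean, ci_low, ci_high)
_GP_TABLE: Dict[str, Tuple[Tuple[float, float, float], ...]] = {
    "AC": ((0.063, 0.057, 0.070), (0.106, 0.097, 0.116), (0.148, 0.138, 0.159)),
    "CO": ((0.054, 0.049, 0.059), (0.082, 0.075, 0.089), (0.121, 0.112, 0.130)),
    "PD": ((0.068, 0.061, 0.076), (0.111, 0.102, 0.122), (0.160, 0.148, 0.173)),
    "IN": ((0.033, 0.030, 0.037), (0.072, 0.066, 0.078), (0.124, 0.115, 0.134)),
    "SE": ((0.046, 0.042, 0.050), (0.068, 0.062, 0.074), (0.098, 0.091, 0.105)),
    "ME": ((0.055, 0.050, 0.060), (0.084, 0.076, 0.092), (0.119, 0.110, 0.129)),
    "AX": ((0.044, 0.040, 0.049), (0.073, 0.067, 0.079), (0.101, 0.094, 0.109)),
}

_MI_TABLE: Dict[str, Tuple[Tuple[float, float, float], ...]] = {
    "AC": ((0.056, 0.049, 0.065), (0.085, 0.076, 0.094), (0.128, 0.115, 0.141)),
    "CO": ((0.055, 0.049, 0.062), (0.082, 0.072, 0.093), (0.123, 0.109, 0.138)),
    "PD": ((0.061, 0.052, 0.070), (0.099, 0.088, 0.111), (0.139, 0.126, 0.154)),
    "IN": ((0.038, 0.033, 0.044), (0.064, 0.057, 0.071), (0.108, 0.098, 0.119)),
    "SE": ((0.045, 0.039, 0.052), (0.063, 0.056, 0.072), (0.098, 0.087, 0.109)),
    "ME": ((0.050, 0.043, 0.057), (0.070, 0.063, 0.079), (0.110, 0.098, 0.122)),
    "AX": ((0.042, 0.036, 0.048), (0.064, 0.056, 0.072), (0.093, 0.083, 0.105)),
}

_SAMPLE_SIZES = {"GP": 504, "MI": 368}
_TABLES = {"GP": _GP_TABLE, "MI": _MI_TABLE}


def _build(name: str) -> ValueSet:
    table = _TABLES[name]
    dec = np.zeros((7, 4))
    lo = np.zeros((7, 4))
    hi = np.zeros((7, 4))
    for i, code in enumerate(DIMENSIONS):
        for lvl, (mean, ci_lo, ci_hi) in enumerate(table[code], start=1):
            dec[i, lvl] = mean
            lo[i, lvl] = ci_lo
            hi[i, lvl] = ci_hi
    return ValueSet(
        name=name,
        n_respondents=_SAMPLE_SIZES[name],
        decrements=dec,
        ci_low=lo,
        ci_high=hi,
        provenance={"source": "published MobQoL-7D value set", "precision": "3 decimals"},
    )


def available_value_sets() -> List[str]:
    return sorted(_TABLES)


def published_value_set(name: str) -> ValueSet:
    """Return the published GP or MI value set with decrements and CIs as printed."""
    key = name.upper()
    if key not in _TABLES:
        raise KeyError(
            f"unknown value set {name!r}; available: {', '.join(available_value_sets())}"
        )
    return _build(key)


# Published top-25 and bottom-25 ranked states:
# (state, gp_utility, mi_utility, difference, gp_rank, mi_rank, rank_difference)
_EXTREME_ROWS: List[Tuple[str, float, float, float, int, int, int]] = [
    ("1111111", 1.000, 1.000, 0.000, 1, 1, 0),
    ("1112111", 0.967, 0.962, 0.005, 2, 2, 0),
    ("1111112", 0.956, 0.958, -0.003, 3, 3, 0),
    ("1111211", 0.954, 0.955, -0.001, 4, 4, 0),
    ("1211111", 0.946, 0.945, 0.001, 5, 6, -1),
    ("1111121", 0.945, 0.950, -0.005, 6, 5, 1),
    ("2111111", 0.937, 0.944, -0.007, 7, 7, 0),
    ("1121111", 0.932, 0.939, -0.007, 8, 8, 0),
    ("1111311", 0.932, 0.937, -0.005, 9, 9, 0),
    ("1113111", 0.928, 0.936, -0.008, 10, 11, -1),
    ("1111113", 0.927, 0.936, -0.009, 11, 10, 1),
    ("1112112", 0.923, 0.920, 0.003, 12, 13, -1),
    ("1112211", 0.921, 0.916, 0.005, 13, 15, -2),
    ("1311111", 0.918, 0.918, 0.000, 14, 14, 0),
    ("1111131", 0.916, 0.930, -0.014, 15, 12, 3),
    ("1212111", 0.913, 0.906, 0.007, 16, 21, -5),
    ("1112121", 0.912, 0.912, 0.000, 17, 18, -1),
    ("1111212", 0.910, 0.913, -0.003, 18, 17, 1),
    ("2112111", 0.904, 0.905, -0.002, 19, 22, -3),
    ("1211112", 0.902, 0.903, -0.001, 20, 24, -4),
    ("1111411", 0.902, 0.902, -0.001, 21, 25, -4),
    ("1111122", 0.901, 0.909, -0.008, 22, 19, 3),
    ("1211211", 0.900, 0.899, 0.001, 23, 29, -6),
    ("1111221", 0.899, 0.905, -0.006, 24, 23, 1),
    ("1111114", 0.899, 0.907, -0.008, 25, 20, 5),
    ("4444243", 0.209, 0.283, -0.074, 16360, 16354, 6),
    ("4443443", 0.209, 0.275, -0.067, 16361, 16364, -3),
    ("4434344", 0.207, 0.275, -0.068, 16362, 16363, -1),
    ("4434443", 0.205, 0.271, -0.066, 16363, 16370, -7),
    ("3444434", 0.205, 0.283, -0.078, 16364, 16355, 9),
    ("4344434", 0.202, 0.281, -0.078, 16365, 16357, 8),
    ("3444344", 0.200, 0.277, -0.078, 16366, 16361, 5),
    ("3444443", 0.198, 0.273, -0.075, 16367, 16366, 1),
    ("4344344", 0.197, 0.276, -0.078, 16368, 16362, 6),
    ("4244444", 0.195, 0.268, -0.073, 16369, 16372, -3),
    ("4344443", 0.195, 0.271, -0.076, 16370, 16368, 2),
    ("4444334", 0.193, 0.274, -0.081, 16371, 16365, 6),
    ("4444424", 0.193, 0.261, -0.068, 16372, 16374, -2),
    ("4444433", 0.191, 0.270, -0.078, 16373, 16371, 2),
    ("4444343", 0.186, 0.265, -0.078, 16374, 16373, 1),
    ("4444442", 0.185, 0.253, -0.067, 16375, 16376, -1),
    ("4444244", 0.181, 0.253, -0.072, 16376, 16375, 1),
    ("4443444", 0.181, 0.245, -0.065, 16377, 16377, 0),
    ("4434444", 0.178, 0.241, -0.064, 16378, 16380, -2),
    ("3444444", 0.170, 0.243, -0.073, 16379, 16378, 1),
    ("4344444", 0.167, 0.241, -0.074, 16380, 16379, 1),
    ("4444434", 0.164, 0.240, -0.077, 16381, 16381, 0),
    ("4444344", 0.158, 0.235, -0.077, 16382, 16382, 0),
    ("4444443", 0.156, 0.230, -0.074, 16383, 16383, 0),
    ("4444444", 0.128, 0.201, -0.072, 16384, 16384, 0),
]

EXTREME_STATE_COLUMNS = [
    "state", "gp_utility", "mi_utility", "difference", "gp_rank", "mi_rank", "rank_difference",
]


def extreme_state_reference() -> pd.DataFrame:
    """The published top/bottom-25 ranked-state table as a DataFrame."""
    return pd.DataFrame(_EXTREME_ROWS, columns=EXTREME_STATE_COLUMNS)
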