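"""CSV/JSON input-output for respondent data, scored tables and provenance.

Respondent CSV schema (header required, UTF-8, '.' decimal point)::

    id, sample, state,
    vas_AC_l2 .. vas_AX_l2, vas_AC_l3 .. vas_AX_l3,   (7 + 7 columns)
    weight_AC .. weight_AX,                            (7 columns)
    most_impactful, anchor_branch, anchor_vas,
    gender, age_band, employment, ethnicity

``anchor_branch`` is ``worst`` (prefers the worst state over dead) or
``dead``.  ``state`` is the 7-digit own-state index.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .puf import (
    AnchoringResponse,
    Demographics,
    LevelRatings,
    RespondentRecord,
    SwingWeights,
    ValidationError,
)
from .states import DIMENSIONS, parse_state_index

__all__ = [
    "RESPONDENT_COLUMNS",
    "read_respondents",
    "write_respondents",
    "respondents_to_frame",
    "read_states_table",
    "write_provenance",
]

_BRANCH_TO_CSV = {"worst_preferred": "worst", "dead_preferred": "dead"}
_BRANCH_FROM_CSV = {v: k for k, v in _BRANCH_TO_CSV.items()}

RESPONDENT_COLUMNS: List[str] = (
    ["id", "sample", "state"]
    + [f"vas_{c}_l2" for c in DIMENSIONS]
    + [f"vas_{c}_l3" for c in DIMENSIONS]
    + [f"weight_{c}" for c in DIMENSIONS]
    + ["most_impactful", "anchor_branch", "anchor_vas", "gender", "age_band",
       "employment", "ethnicity"]
)


class SchemaError(ValueError):
    """The file's header does not match the documented schema."""


def respondents_to_frame(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: Dict[str, object] = {
            "id": r.id,
            "sample": r.sample,
            "state": r.own_state.index,
        }
        for c in DIMENSIONS:
            row[f"vas_{c}_l2"] = r.level_ratings.vas_level2[c]
        for c in DIMENSIONS:
            row[f"vas_{c}_l3"] = r.level_ratings.vas_level3[c]
        for c in DIMENSIONS:
            row[f"weight_{c}"] = r.swing_weights.raw[c]
        row["most_impactful"] = r.swing_weights.most_impactful
        row["anchor_branch"] = _BRANCH_TO_CSV[r.anchoring.branch]
        row["anchor_vas"] = r.anchoring.vas_position
        row["gender"] = r.demographics.gender
        row["age_band"] = r.demographics.age_band
        row["employment"] = r.demographics.employment or ""
        row["ethnicity"] = r.demographics.ethnicity or ""
        rows.append(row)
    return pd.DataFrame(rows, columns=RESPONDENT_COLUMNS)


def write_respondents(records: Sequence[RespondentRecord], path: Union[str, Path]) -> None:
    respondents_to_frame(records).to_csv(path, index=False)


def _row_to_record(row: pd.Series, rownum: int) -> RespondentRecord:
    try:
        ratings = LevelRatings(
            vas_level2={c: float(row[f"vas_{c}_l2"]) for c in DIMENSIONS},
            vas_level3={c: float(row[f"vas_{c}_l3"]) for c in DIMENSIONS},
        )
        weights = SwingWeights(
            raw={c: float(row[f"weight_{c}"]) for c in DIMENSIONS},
            most_impactful=str(row["most_impactful"]),
        )
        anchor_branch = str(row["anchor_branch"])
        if anchor_branch not in _BRANCH_FROM_CSV:
            raise ValidationError(
                f"anchor_branch must be 'worst' or 'dead', got {anchor_branch!r}"
            )
        anchoring = AnchoringResponse(
            branch=_BRANCH_FROM_CSV[anchor_branch],
            vas_position=float(row["anchor_vas"]),
        )
        emp = str(row.get("employment", "") or "")
        eth = str(row.get("ethnicity", "") or "")
        return RespondentRecord(
            id=str(row["id"]),
            sample=str(row["sample"]),
            own_state=parse_state_index(str(row["state"])),
            level_ratings=ratings,
            swing_weights=weights,
            anchoring=anchoring,
            demographics=Demographics(
                gender=str(row["gender"]),
                age_band=str(row["age_band"]),
                employment=emp or None,
                ethnicity=eth or None,
            ),
        )
    except (ValueError, KeyError) as exc:
        raise ValidationError(f"row {rownum}: {exc}") from exc


def read_respondents(path: Union[str, Path]) -> List[RespondentRecord]:
    """Read typed respondent records; raises with the row number on bad rows."""
    df = pd.read_csv(
        path, dtype={"state": str}, keep_default_na=False, float_precision="round_trip"
    )
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns and c not in ("employment", "ethnicity")]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # header is line 1
        records.append(_row_to_record(row, i))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate respondent id(s): {', '.join(dupes[:5])}")
    return records


def read_states_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a table of health states to score.

    Accepts either a ``state`` column of 7-digit indices or seven per-item
    columns named by the dimension codes (AC..AX); in the latter case a
    ``state`` column is synthesised.  All other columns pass through.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "state" not in df.columns:
        if all(c in df.columns for c in DIMENSIONS):
            df["state"] = df[list(DIMENSIONS)].agg("".join, axis=1)
        else:
            raise SchemaError(
                f"{path}: need a 'state' column or the seven item columns {DIMENSIONS}"
            )
    return df


def write_provenance(
    out_dir: Union[str, Path],
    command: str,
    params: Dict[str, object],
    filename: str = "provenance.json",
) -> Path:
    """Write a machine-readable record sufficient to re-run a command.

    Deliberately excludes wall-clock timestamps so repeated runs with the
    same seed produce byte-identical output directories.
    """
    import numpy
    import pandas

    record = {
        "command": command,
        "params": params,
        "versions": {
            "mobqol": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
        },
    }
    out = Path(out_dir) / filename
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return out
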