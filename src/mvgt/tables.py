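"""Schema for assessment tables.

An assessment table holds one multivariate observation per (trainee,
procedure) cell: two 4-level autonomy ratings (faculty and trainee) and two
5-level performance ratings (faculty and trainee), plus the trainee's
postgraduate-year (PGY) label and the case-complexity stratum.
"""

from __future__ import annotations

import pandas as pd

from .errors import TableValidationError

#: Fixed order of the four score variables everywhere in the package:
#: faculty autonomy, trainee autonomy, faculty performance, trainee performance.
SCORE_COLUMNS = ("score_fa", "score_ta", "score_fp", "score_tp")

#: Number of ordinal levels per score variable (autonomy 1-4, performance 1-5).
SCALE_LEVELS = (4, 4, 5, 5)

#: Human-readable names, index-aligned with SCORE_COLUMNS.
VARIABLE_NAMES = (
    "faculty_autonomy",
    "trainee_autonomy",
    "faculty_performance",
    "trainee_performance",
)

COMPLEXITY_LEVELS = ("easiest", "average", "hardest")

ID_COLUMNS = ("trainee_id", "procedure_id", "pgy", "complexity")

ALL_COLUMNS = ID_COLUMNS + SCORE_COLUMNS

#: Items pairing the faculty and trainee variables (column indices).
ITEM_VARIABLE_PAIRS = {"autonomy": (0, 1), "performance": (2, 3)}


def validate_table(table: pd.DataFrame, ordinal: bool | None = None) -> pd.DataFrame:
    """Validate an assessment table against the schema.

    Parameters
    ----------
    table
        Candidate assessment table.
    ordinal
        If True, enforce integer scores within each variable's legal levels.
        If None (default), ordinal checks run only when every score column is
        integer-typed (latent continuous tables skip them).

    Returns
    -------
    The validated table (unchanged).

    Raises
    ------
    TableValidationError
        On missing columns, duplicate cells, NaN scores, or illegal levels.
    """
    missing = [c for c in ALL_COLUMNS if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    dup = table.duplicated(subset=["trainee_id", "procedure_id"])
    if dup.any():
        first = table.loc[dup, ["trainee_id", "procedure_id"]].iloc[0]
        raise TableValidationError(
            "duplicate (trainee_id, procedure_id) cell: "
            f"({first['trainee_id']}, {first['procedure_id']})"
        )
    scores = table[list(SCORE_COLUMNS)]
    if scores.isna().any().any():
        raise TableValidationError("score columns must not contain missing values")
    if ordinal is None:
        ordinal = all(
            pd.api.types.is_integer_dtype(scores[c]) for c in SCORE_COLUMNS
        )
    if ordinal:
        for col, levels in zip(SCORE_COLUMNS, SCALE_LEVELS):
            v = scores[col]
            if ((v < 1) | (v > levels) | (v != v.round())).any():
                bad = v[(v < 1) | (v > levels) | (v != v.round())].iloc[0]
                raise TableValidationError(
                    f"{col}: value {bad!r} outside legal levels 1..{levels}"
                )
    return table


def is_fully_crossed(table: pd.DataFrame) -> bool:
    """True when every trainee is observed on every procedure exactly once."""
    n_t = table["trainee_id"].nunique()
    n_p = table["procedure_id"].nunique()
    return len(table) == n_t * n_p


def score_matrix(table: pd.DataFrame):
    """Return the N x 4 float array of scores in the fixed variable order."""
    return table[list(SCORE_COLUMNS)].to_numpy(dtype=float)
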