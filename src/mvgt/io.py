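"""CSV loading/writing with validation, and report serialization helpers."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableValidationError
from .gstudy import EFFECTS, GStudyComponents, proportion_table
from .tables import (
    ALL_COLUMNS,
    SCALE_LEVELS,
    SCORE_COLUMNS,
    VARIABLE_NAMES,
    validate_table,
)

logger = logging.getLogger(__name__)


def load_assessments(path: str | Path) -> pd.DataFrame:
    """Load and validate an assessment CSV.

    Rows with any missing score are dropped with a logged count (the
    pairing rule: the multivariate analysis needs the full four-score
    vector).  Illegal ordinal levels are rejected with the offending line
    number; the file line number accounts for the header row.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TableValidationError(f"{path}: empty input file") from None
    missing_cols = [c for c in ALL_COLUMNS if c not in table.columns]
    if missing_cols:
        raise TableValidationError(
            f"{path}: malformed header, missing columns {missing_cols}"
        )
    if table.empty:
        raise TableValidationError(f"{path}: no data rows")

    incomplete = table[list(SCORE_COLUMNS)].isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "%s: dropped %d incomplete row(s) (pairing rule)",
            path,
            int(incomplete.sum()),
        )
        table = table[~incomplete]
    if table.empty:
        raise TableValidationError(f"{path}: all rows incomplete")

    scores = table[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    ordinal = bool(np.all(scores == np.round(scores)))
    if ordinal:
        for j, (col, levels) in enumerate(zip(SCORE_COLUMNS, SCALE_LEVELS)):
            bad = (scores[:, j] < 1) | (scores[:, j] > levels)
            if bad.any():
                row = table.index[np.flatnonzero(bad)[0]]
                raise TableValidationError(
                    f"{path}, line {row + 2}: {col} = "
                    f"{scores[np.flatnonzero(bad)[0], j]:g} outside legal "
                    f"levels 1..{levels}"
                )
        table = table.astype({c: int for c in SCORE_COLUMNS})
    table = table.reset_index(drop=True)
    return validate_table(table, ordinal=ordinal)


def write_assessments(table: pd.DataFrame, path: str | Path) -> None:
    """Write an assessment table with the canonical header, full precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, columns=list(ALL_COLUMNS))


def write_components_json(components: GStudyComponents, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(components.to_dict(), indent=2) + "\n")


def read_components_json(path: str | Path) -> GStudyComponents:
    return GStudyComponents.from_dict(json.loads(Path(path).read_text()))


def components_report(components: GStudyComponents) -> pd.DataFrame:
    """G-study variance components and percent-of-total per variable.

    One column per score variable; rows are the three effects, each cell
    "variance (proportion%)" with 3-decimal variances and 1-decimal
    percentages.
    """
    rows = {}
    props = [proportion_table(components, v) for v in range(4)]
    for k, eff in enumerate(EFFECTS):
        rows[f"sigma2({eff})"] = [
            f"{components.matrix(eff)[v, v]:.3f} ({props[v][k]:.1f})"
            for v in range(4)
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(VARIABLE_NAMES)
    )


def dstudy_report(result) -> pd.DataFrame:
    """Composite D-study summary with display rounding (3 decimals)."""
    return pd.DataFrame(
        {
            "value": [
                round(result.universe_score_variance, 3),
                round(result.absolute_error_variance, 3),
                round(result.relative_error_variance, 3),
                round(result.gen_coefficient, 3),
                round(result.dependability, 3),
                result.ci95_margin,
            ]
        },
        index=[
            "universe_score_variance",
            "absolute_error_variance",
            "relative_error_variance",
            "generalizability_coefficient",
            "index_of_dependability",
            "paper-margin (1 SEM)",
        ],
    )


def curve_csv(results, path: str | Path) -> None:
    """Write a (n_p, Erho2, Phi, SEM) curve consumable by any plotter."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "n_p": [r.n_p for r in results],
            "gen_coefficient": [r.gen_coefficient for r in results],
            "dependability": [r.dependability for r in results],
            "sem_absolute": [r.sem_absolute for r in results],
        }
    )
    df.to_csv(path, index=False)
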