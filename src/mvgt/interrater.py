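"""Faculty-trainee agreement: role means and dis-attenuated correlation.

The dis-attenuated correlation is the correlation of universe (true)
scores, read directly off the trainee-effect covariance matrix of the
multivariate G study:

    rho = sigma_t[u, v] / sqrt(sigma_t[u, u] * sigma_t[v, v])

for the faculty/trainee variable pair of an item.  Because it is built
from component estimates it can stray outside [-1, 1]; such values are
clipped with a warning and the raw value logged.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd

from .errors import MvgtError, UndefinedStatisticError
from .gstudy import GStudyComponents
from .tables import ITEM_VARIABLE_PAIRS, SCORE_COLUMNS, score_matrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class InterRaterResult:
    item: str
    stratum: str
    mean_faculty: float
    mean_trainee: float
    disattenuated_r: float
    observed_r: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def disattenuated_correlation(
    components: GStudyComponents, item: str
) -> float:
    """Universe-score correlation between the faculty and trainee ratings."""
    if item not in ITEM_VARIABLE_PAIRS:
        raise MvgtError(f"item must be one of {sorted(ITEM_VARIABLE_PAIRS)}")
    u, v = ITEM_VARIABLE_PAIRS[item]
    var_u = components.sigma_t[u, u]
    var_v = components.sigma_t[v, v]
    if var_u <= 0 or var_v <= 0:
        raise UndefinedStatisticError(
            f"zero universe-score variance for item {item!r}; "
            "dis-attenuated correlation undefined"
        )
    rho = components.sigma_t[u, v] / math.sqrt(var_u * var_v)
    if abs(rho) > 1.0:
        logger.warning(
            "dis-attenuated correlation %.4f for item %s outside [-1, 1]; "
            "clipped",
            rho,
            item,
        )
        rho = math.copysign(1.0, rho)
    return float(rho)


def observed_correlation(table: pd.DataFrame, item: str) -> float:
    """Raw Pearson correlation of the two observed ratings of an item."""
    u, v = ITEM_VARIABLE_PAIRS[item]
    y = score_matrix(table)
    return float(np.corrcoef(y[:, u], y[:, v])[0, 1])


def role_means(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean rating per item and rater role.

    Returns ``{"autonomy": {"faculty": ..., "trainee": ...},
    "performance": {...}}``.
    """
    if table.empty:
        raise MvgtError("role_means requires a nonempty table")
    y = score_matrix(table)
    out = {}
    for item, (u, v) in ITEM_VARIABLE_PAIRS.items():
        out[item] = {
            "faculty": float(y[:, u].mean()),
            "trainee": float(y[:, v].mean()),
        }
    return out


def interrater_report(
    table: pd.DataFrame, components: GStudyComponents, stratum: str
) -> list[InterRaterResult]:
    """Role means plus dis-attenuated and observed correlations per item."""
    means = role_means(table)
    results = []
    for item in ITEM_VARIABLE_PAIRS:
        results.append(
            InterRaterResult(
                item=item,
                stratum=stratum,
                mean_faculty=means[item]["faculty"],
                mean_trainee=means[item]["trainee"],
                disattenuated_r=disattenuated_correlation(components, item),
                observed_r=observed_correlation(table, item),
            )
        )
    return results
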