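"""Dataset-construction rules: stratification and balanced thinning.

The construction mirrors a two-rule design: drop procedures rated by too
few distinct trainees, drop trainees left with too few procedures, then
thin every surviving trainee to exactly ``procedures_per_trainee``
uniformly sampled procedures.  Both filters are applied once, in that
order, before thinning.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import DesignInfeasibleError, MvgtError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SamplingConfig:
    """Balanced-sampling parameters.

    ``procedures_per_trainee`` is the target number of procedures kept per
    trainee; ``min_trainees_per_procedure`` is the distinct-trainee
    threshold a procedure must meet to stay in the design.
    """

    procedures_per_trainee: int = 3
    min_trainees_per_procedure: int = 50
    complexity_stratum: str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.procedures_per_trainee < 1:
            raise MvgtError("procedures_per_trainee must be >= 1")
        if self.min_trainees_per_procedure < 1:
            raise MvgtError("min_trainees_per_procedure must be >= 1")


def stratify(table: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    """Partition rows by (pgy, complexity).

    Returns a dict keyed by (pgy, complexity); the union of the values
    equals the input and each value is homogeneous in both labels.
    """
    strata = {}
    for key, sub in table.groupby(["pgy", "complexity"], sort=True, observed=True):
        strata[(key[0], key[1])] = sub.reset_index(drop=True)
    return strata


def sample_balanced(table: pd.DataFrame, config: SamplingConfig) -> pd.DataFrame:
    """Thin a single-stratum table to a balanced design.

    Steps, applied once in order:

    1. drop procedures assessed by fewer than
       ``min_trainees_per_procedure`` distinct trainees;
    2. drop trainees left with fewer than ``procedures_per_trainee``
       procedures;
    3. for each surviving trainee keep exactly ``procedures_per_trainee``
       procedures, sampled uniformly without replacement under the seed.

    Raises
    ------
    DesignInfeasibleError
        Naming the filter that emptied the design.
    """
    if table.empty:
        raise DesignInfeasibleError("input", "stratum has no rows")

    per_proc = table.groupby("procedure_id")["trainee_id"].nunique()
    keep_procs = per_proc.index[per_proc >= config.min_trainees_per_procedure]
    n_dropped_procs = per_proc.size - keep_procs.size
    out = table[table["procedure_id"].isin(keep_procs)]
    if out.empty:
        raise DesignInfeasibleError(
            "procedure-threshold",
            f"all {per_proc.size} procedures have fewer than "
            f"{config.min_trainees_per_procedure} distinct trainees",
        )

    per_trainee = out.groupby("trainee_id")["procedure_id"].nunique()
    keep_trainees = per_trainee.index[
        per_trainee >= config.procedures_per_trainee
    ]
    n_dropped_trainees = per_trainee.size - keep_trainees.size
    out = out[out["trainee_id"].isin(keep_trainees)]
    if out.empty:
        raise DesignInfeasibleError(
            "trainee-threshold",
            f"no trainee retains >= {config.procedures_per_trainee} procedures",
        )
    logger.info(
        "sample_balanced: dropped %d procedures (<%d trainees), "
        "%d trainees (<%d procedures)",
        n_dropped_procs,
        config.min_trainees_per_procedure,
        n_dropped_trainees,
        config.procedures_per_trainee,
    )

    rng = np.random.default_rng(config.seed)
    k = config.procedures_per_trainee
    kept_indices = []
    for trainee, sub in out.groupby("trainee_id", sort=True):
        sub = sub.sort_values("procedure_id")
        if len(sub) == k:
            kept_indices.append(sub.index.to_numpy())
        else:
            pick = rng.choice(len(sub), size=k, replace=False)
            kept_indices.append(sub.index.to_numpy()[np.sort(pick)])
    result = out.loc[np.concatenate(kept_indices)]
    return result.reset_index(drop=True)
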