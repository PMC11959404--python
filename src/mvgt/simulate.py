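"""Synthetic rating-data generator with known variance/covariance structure.

The generative model is a two-way crossed random-effects design with one
multivariate observation per realized (trainee, procedure) cell:

    latent_ij = grand_means + t_i + p_j + e_ij

where t_i ~ MVN(0, sigma_t), p_j ~ MVN(0, sigma_p) and e_ij ~ MVN(0,
sigma_tp); the interaction and residual are confounded in ``sigma_tp``
because the design has a single observation per cell.  Continuous (latent)
output is exact for parameter-recovery tests; optional per-variable
cutpoints discretize each latent score to its ordinal scale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import NotPositiveSemidefiniteError, MvgtError
from .tables import (
    ALL_COLUMNS,
    COMPLEXITY_LEVELS,
    SCALE_LEVELS,
    SCORE_COLUMNS,
)

_PSD_TOL = 1e-10

_EFFECTS = ("t", "p", "tp")


def _as_cov(matrix, effect: str) -> np.ndarray:
    """Symmetrize and PSD-check a 4x4 ground-truth covariance matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise MvgtError(f"sigma_{effect} must be 4x4, got shape {m.shape}")
    m = (m + m.T) / 2.0
    min_eig = float(np.linalg.eigvalsh(m)[0])
    if min_eig < -_PSD_TOL * max(1.0, float(np.abs(m).max())):
        raise NotPositiveSemidefiniteError(effect, min_eig)
    return m


@dataclasses.dataclass
class SimulationConfig:
    """Ground truth and design sizes for :func:`generate_dataset`.

    ``cutpoints`` maps a score column to its ordered thresholds; an empty
    dict keeps all variables continuous.  ``procedures_per_trainee = 0``
    means fully crossed.
    """

    n_trainees: int
    n_procedures: int
    sigma_t: np.ndarray
    sigma_p: np.ndarray
    sigma_tp: np.ndarray
    grand_means: np.ndarray
    procedures_per_trainee: int = 0
    cutpoints: dict = dataclasses.field(default_factory=dict)
    pgy_label: int = 5
    complexity_label: str = "average"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trainees < 1 or self.n_procedures < 1:
            raise MvgtError("n_trainees and n_procedures must be positive")
        if not 0 <= self.procedures_per_trainee <= self.n_procedures:
            raise MvgtError(
                "procedures_per_trainee must be in [0, n_procedures] "
                f"(got {self.procedures_per_trainee} with "
                f"n_procedures={self.n_procedures})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise MvgtError("missing_rate must lie in [0, 1)")
        if not 1 <= int(self.pgy_label) <= 5:
            raise MvgtError("pgy_label must be an integer in 1..5")
        if self.complexity_label not in COMPLEXITY_LEVELS:
            raise MvgtError(
                f"complexity_label must be one of {COMPLEXITY_LEVELS}"
            )
        self.sigma_t = _as_cov(self.sigma_t, "t")
        self.sigma_p = _as_cov(self.sigma_p, "p")
        self.sigma_tp = _as_cov(self.sigma_tp, "tp")
        self.grand_means = np.asarray(self.grand_means, dtype=float).reshape(4)
        for col, cuts in self.cutpoints.items():
            if col not in SCORE_COLUMNS:
                raise MvgtError(f"cutpoints key {col!r} is not a score column")
            levels = SCALE_LEVELS[SCORE_COLUMNS.index(col)]
            c = np.asarray(cuts, dtype=float)
            if c.size != levels - 1 or np.any(np.diff(c) <= 0):
                raise MvgtError(
                    f"cutpoints for {col} must be {levels - 1} strictly "
                    "increasing thresholds"
                )

    @property
    def ordinal(self) -> bool:
        return bool(self.cutpoints)


def default_cutpoints() -> dict:
    """Equal-width thresholds centered on each scale's midpoint."""
    cuts = {}
    for col, levels in zip(SCORE_COLUMNS, SCALE_LEVELS):
        cuts[col] = [k + 0.5 for k in range(1, levels)]
    return cuts


def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    # eigh factorization tolerates singular (e.g. all-zero) covariances
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((n, 4))
    return z @ (v * np.sqrt(w)).T


def generate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Generate an assessment table from known ground truth.

    The draw order is fixed (trainee effects, procedure effects, linkage,
    cell residuals, missingness) so that an identical config always yields a
    byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    n_t, n_p = config.n_trainees, config.n_procedures

    t_eff = _draw_mvn(rng, config.sigma_t, n_t)
    p_eff = _draw_mvn(rng, config.sigma_p, n_p)

    k = config.procedures_per_trainee
    if k == 0:
        ti = np.repeat(np.arange(n_t), n_p)
        pi = np.tile(np.arange(n_p), n_t)
    else:
        rows_t, rows_p = [], []
        for i in range(n_t):
            chosen = np.sort(rng.choice(n_p, size=k, replace=False))
            rows_t.append(np.full(k, i))
            rows_p.append(chosen)
        ti = np.concatenate(rows_t)
        pi = np.concatenate(rows_p)

    e_eff = _draw_mvn(rng, config.sigma_tp, len(ti))
    latent = config.grand_means[None, :] + t_eff[ti] + p_eff[pi] + e_eff

    if config.missing_rate > 0:
        keep = rng.random(len(ti)) >= config.missing_rate
        ti, pi, latent = ti[keep], pi[keep], latent[keep]

    data = {
        "trainee_id": np.char.add("T", np.char.zfill((ti + 1).astype(str), 4)),
        "procedure_id": np.char.add("P", np.char.zfill((pi + 1).astype(str), 4)),
        "pgy": np.full(len(ti), int(config.pgy_label)),
        "complexity": np.full(len(ti), config.complexity_label, dtype=object),
    }
    table = pd.DataFrame(data)
    for j, col in enumerate(SCORE_COLUMNS):
        values = latent[:, j]
        if col in config.cutpoints:
            cuts = np.asarray(config.cutpoints[col], dtype=float)
            table[col] = np.searchsorted(cuts, values, side="left") + 1
        else:
            table[col] = values
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# config (de)serialization

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("sigma_t", "sigma_p", "sigma_tp", "grand_means"):
        d[key] = np.asarray(d[key]).tolist()
    d["cutpoints"] = {k: list(map(float, v)) for k, v in config.cutpoints.items()}
    return d


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    d = config_to_dict(config)
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))
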