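"""End-to-end analysis pipeline.

Sequence per stratum: stratify -> balanced sampling -> G study (balanced
or REML, auto-detected) -> composite D study, reliability curve and
minimum-procedures search -> inter-rater statistics.  Outputs a bundle of
JSON/CSV reports plus a run manifest; identical config and seed yield an
identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .dstudy import CompositeWeights, composite_dstudy, dstudy_curve, min_procedures
from .errors import MvgtError
from .gstudy import estimate
from .interrater import interrater_report
from .io import (
    components_report,
    curve_csv,
    dstudy_report,
    write_components_json,
)
from .sampling import SamplingConfig, sample_balanced, stratify
from .simulate import SimulationConfig, config_to_dict, generate_dataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed for a reproducible end-to-end run."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    sampling: SamplingConfig = dataclasses.field(default_factory=SamplingConfig)
    weights: CompositeWeights = dataclasses.field(default_factory=CompositeWeights)
    threshold: float = 0.8
    criterion: str = "dependability"
    n_max: int = 100
    curve_max: int = 30
    output_dir: str = "mvgt_out"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise MvgtError("threshold must lie in (0, 1)")
        if self.n_max < 1:
            raise MvgtError("n_max must be >= 1")
        if self.input_path is None and self.simulation is None:
            raise MvgtError("provide either input_path or a simulation config")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "simulation": (
                config_to_dict(self.simulation) if self.simulation else None
            ),
            "sampling": dataclasses.asdict(self.sampling),
            "weights": self.weights.w.tolist(),
            "threshold": self.threshold,
            "criterion": self.criterion,
            "n_max": self.n_max,
            "curve_max": self.curve_max,
            "seed": self.seed,
        }


def _stratum_tag(key: tuple) -> str:
    return f"pgy{key[0]}_{key[1]}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    A failure in one stratum (e.g. an infeasible design after filtering)
    is recorded and does not abort the remaining strata.
    """
    from .io import load_assessments  # local import to keep cycles out

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        table = load_assessments(config.input_path)
    else:
        table = generate_dataset(config.simulation)

    strata = stratify(table)
    summary = {}
    for key in sorted(strata, key=lambda k: (str(k[0]), str(k[1]))):
        tag = _stratum_tag(key)
        sub = strata[key]
        if sub.empty:
            summary[tag] = {"status": "skipped: no data"}
            continue
        try:
            sampled = sample_balanced(sub, config.sampling)
            components = estimate(sampled)
            n_design = config.sampling.procedures_per_trainee
            d_at_design = composite_dstudy(components, config.weights, n_design)
            n_star = min_procedures(
                components,
                config.weights,
                config.threshold,
                config.criterion,
                config.n_max,
            )
            curve = dstudy_curve(
                components, config.weights, range(1, config.curve_max + 1)
            )
            inter = interrater_report(sampled, components, tag)

            write_components_json(components, out / f"components_{tag}.json")
            components_report(components).to_csv(out / f"gstudy_{tag}.csv")
            dstudy_report(d_at_design).to_csv(out / f"dstudy_{tag}.csv")
            curve_csv(curve, out / f"curve_{tag}.csv")
            pd.DataFrame([r.to_dict() for r in inter]).to_csv(
                out / f"interrater_{tag}.csv", index=False
            )
            summary[tag] = {
                "status": "ok",
                "n_trainees": int(components.n_trainees),
                "n_rows": int(len(sampled)),
                "dependability_at_design": round(d_at_design.dependability, 6),
                "gen_coefficient_at_design": round(
                    d_at_design.gen_coefficient, 6
                ),
                "min_procedures": (
                    int(n_star) if n_star is not None else "not attainable"
                ),
            }
        except MvgtError as exc:
            logger.error("stratum %s failed: %s", tag, exc)
            summary[tag] = {"status": f"failed: {exc}"}

    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": config_hash,
        "strata": summary,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
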