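"""End-to-end pipeline: raw edge list + expression CSV -> influence ranking.

Stages mirror the analysis workflow: read inputs, extract the
high-confidence subnetwork, attach expression scores, weight the edges
(LP or constant), rank all nodes by Monte-Carlo coverage, and write the
artifacts plus a provenance JSON sufficient to replay the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .diffusion import DEFAULT_N_SIM
from .errors import MirCascadeError, ValidationError
from .model import InfluenceModel
from .network import write_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the method's published settings."""

    threshold: float = 0.90
    weight_mode: str = "optimize"  # optimize | constant
    constant_weight: float = 0.01
    n_sim: int = DEFAULT_N_SIM
    rng_seed: int = 0
    top_k: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(f"threshold {self.threshold} outside [0, 1]")
        if self.weight_mode not in ("optimize", "constant"):
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")
        if not 0.0 < self.constant_weight <= 1.0:
            raise ValidationError(
                f"constant_weight {self.constant_weight} outside (0, 1]"
            )
        if self.n_sim < 1:
            raise ValidationError(f"n_sim must be >= 1, got {self.n_sim}")
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {self.top_k}")
        if self.log_level.upper() not in (
            "DEBUG", "INFO", "WARNING", "ERROR", "CRITICAL",
        ):
            raise ValidationError(f"unknown log_level {self.log_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    edges_path: str | Path,
    expression_path: Optional[str | Path],
    out_dir: str | Path,
    disease_id: Optional[str] = None,
) -> dict:
    """Run build -> weights -> coverage and write all artifacts.

    Writes the high-confidence network, the weighted network, the ranking CSV
    and ``provenance.json`` under ``out_dir``; returns the provenance record.
    Raises ``MirCascadeError`` subclasses with a stage-named message on
    failure.
    """
    config.validate()
    edges_path = Path(edges_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read_inputs"
    try:
        model = InfluenceModel.from_csv(
            str(edges_path),
            str(expression_path) if expression_path else None,
            disease_id=disease_id,
            threshold=config.threshold,
        )
        stage = "fit_weights"
        results = model.fit(
            method=config.weight_mode, constant_weight=config.constant_weight
        )
        write_network(results.hc_network, out_dir / "dmin_hc.csv")
        write_network(results.network, out_dir / "dmin_hce_weighted.csv")
        stage = "rank_coverage"
        ranking = results.rank(n_sim=config.n_sim, rng=config.rng_seed)
        ranking.to_csv(out_dir / "ranking.csv")
    except MirCascadeError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "disease_id": results.network.disease_id,
        "inputs": {
            str(edges_path): _sha256(edges_path),
            **(
                {str(expression_path): _sha256(Path(expression_path))}
                if expression_path
                else {}
            ),
        },
        "diagnostics": results.diagnostics,
        "top_ranking": ranking.top(config.top_k).to_dict(orient="records"),
    }
    if results.lp_solution is not None:
        provenance["lp"] = results.lp_solution.to_dict()
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return provenance
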