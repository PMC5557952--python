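"""Synthetic networks and expression tables for tests, demos and benchmarks.

Everything here is generated programmatically and reproducibly from an
integer seed; no external data is required.  Included generators:

* the five-node worked-example network used throughout the documentation,
* Erdos-Renyi-style random disease networks with configurable weight and
  expression distributions,
* planted-influencer networks with a known dominant hub (ground truth for
  ranking-recovery tests),
* expression tables with replicated (miRNA, disease) rows emulating
  multi-study fold-change databases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .network import Dmin, ExpressionRecord, ExpressionTable

logger = logging.getLogger(__name__)

#: distribution specs are tuples: ("uniform01",), ("constant", w),
#: ("high_confidence",), ("lognormal", mu, sigma), ("fixed", e)


@dataclass
class FixtureConfig:
    """Parameters of a random disease network."""

    n_nodes: int = 10
    edge_density: float = 0.3
    weight_distribution: tuple = ("uniform01",)
    expression_distribution: tuple = ("lognormal", 0.0, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValidationError(
                f"edge_density must be in (0, 1], got {self.edge_density}"
            )


def _draw_weights(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform01":
        return rng.uniform(0.0, 1.0, size)
    if kind == "constant":
        w = float(spec[1])
        if not 0.0 < w <= 1.0:
            raise ValidationError(f"constant weight must be in (0, 1], got {w}")
        return np.full(size, w)
    if kind == "high_confidence":
        return rng.uniform(0.9, 1.0, size)
    raise ValidationError(f"unknown weight distribution {spec!r}")


def _draw_expressions(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "lognormal":
        mu, sigma = float(spec[1]), float(spec[2])
        return rng.lognormal(mu, sigma, size)
    if kind == "fixed":
        e = float(spec[1])
        if e < 0:
            raise ValidationError(f"fixed expression must be >= 0, got {e}")
        return np.full(size, e)
    raise ValidationError(f"unknown expression distribution {spec!r}")


def _node_ids(n: int, prefix: str = "mir-") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{k:0{width}d}" for k in range(1, n + 1)]


def toy_cascade_fixture(
    weights: Optional[dict[tuple[str, str], float]] = None,
    disease_id: str = "toy",
) -> Dmin:
    """The five-node worked-example cascade network.

    Edges 1->2 (0.5) and 1->3 (0.9) carry the published weights; the
    remaining edges 3->4, 3->5 and 5->4 default to 0.5 and can be overridden
    via ``weights`` (keys like ("n1", "n2")).
    """
    base = {
        ("n1", "n2"): 0.5,
        ("n1", "n3"): 0.9,
        ("n3", "n4"): 0.5,
        ("n3", "n5"): 0.5,
        ("n5", "n4"): 0.5,
    }
    if weights:
        unknown = set(weights) - set(base)
        if unknown:
            raise ValidationError(f"unknown edges in override: {sorted(unknown)}")
        base.update(weights)
    net = Dmin(disease_id)
    for (u, v), w in base.items():
        net.add_edge(u, v, w)
    return net


def generate_random_dmin(config: FixtureConfig, disease_id: str = "synthetic") -> Dmin:
    """Directed Erdos-Renyi-style network with random weights and expressions."""
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_nodes
    ids = _node_ids(n)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    mask = rng.random(len(pairs)) < config.edge_density
    chosen = [p for p, m in zip(pairs, mask) if m]
    if not chosen:
        logger.warning(
            "density %g on %d nodes produced no edges", config.edge_density, n
        )
    w = _draw_weights(config.weight_distribution, len(chosen), rng)
    e = _draw_expressions(config.expression_distribution, n, rng)
    net = Dmin(disease_id)
    for k, node in enumerate(ids):
        net.add_node(node, expression=float(e[k]))
    for k, (i, j) in enumerate(chosen):
        net.add_edge(ids[i], ids[j], float(w[k]))
    return net


def planted_influencer_network(
    n_nodes: int = 20,
    hub_out_degree: int = 15,
    hub_p: float = 0.9,
    background_p: float = 0.05,
    rng_seed: int = 0,
    background_density: float = 0.05,
    disease_id: str = "planted",
) -> tuple[Dmin, str]:
    """Network with one designated hub of dominant expected spread.

    The hub gets ``hub_out_degree`` out-edges at the high weight ``hub_p``;
    sparse background edges among the remaining nodes carry the low weight
    ``background_p``.  Returns the network and the hub's id (ground truth
    for ranking recovery).
    """
    if n_nodes < 2:
        raise ValidationError(f"n_nodes must be >= 2, got {n_nodes}")
    if hub_out_degree > n_nodes - 1:
        raise ValidationError(
            f"hub_out_degree {hub_out_degree} exceeds n_nodes-1 = {n_nodes - 1}"
        )
    if not hub_p > background_p:
        raise ValidationError(
            f"hub_p ({hub_p}) must exceed background_p ({background_p})"
        )
    if not (0.0 < hub_p <= 1.0 and 0.0 <= background_p <= 1.0):
        raise ValidationError("edge weights must lie in [0, 1] with hub_p > 0")
    rng = np.random.default_rng(rng_seed)
    hub = "hub"
    others = _node_ids(n_nodes - 1)
    net = Dmin(disease_id)
    net.graph.add_node(hub)
    for node in others:
        net.graph.add_node(node)
    targets = rng.choice(len(others), size=hub_out_degree, replace=False)
    for t in sorted(targets):
        net.add_edge(hub, others[t], hub_p)
    if background_p > 0:
        for i, u in enumerate(others):
            for j, v in enumerate(others):
                if i != j and rng.random() < background_density:
                    net.add_edge(u, v, background_p)
    return net, hub


def generate_expression_table(
    diseases: Sequence[str],
    mirnas_per_disease: int,
    replicates: int = 2,
    replicate_fraction: float = 0.3,
    distribution: tuple = ("lognormal", 0.0, 1.0),
    rng_seed: int = 0,
) -> ExpressionTable:
    """Expression table with a fraction of replicated (miRNA, disease) pairs.

    Fold changes are drawn from the configured distribution; log-normal draws
    fall both above and below 1, emulating a mix of up- and down-regulation.
    A ``replicate_fraction`` of pairs receive ``replicates`` rows each (one
    per pseudo-study), the rest a single row.
    """
    if mirnas_per_disease < 1 or replicates < 1 or not diseases:
        raise ValidationError("all fixture counts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    records: list[ExpressionRecord] = []
    mirnas = _node_ids(mirnas_per_disease)
    for disease in diseases:
        for mirna in mirnas:
            reps = (
                replicates if rng.random() < replicate_fraction else 1
            )
            fcs = _draw_expressions(distribution, reps, rng)
            fcs = np.maximum(fcs, 1e-12)  # fold changes must stay positive
            for s, fc in enumerate(fcs, start=1):
                records.append(
                    ExpressionRecord(
                        mirna_id=mirna,
                        disease_id=disease,
                        fold_change=float(fc),
                        regulation="up" if fc >= 1 else "down",
                        study_id=f"study{s}" if reps > 1 else None,
                    )
                )
    return ExpressionTable(records)
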