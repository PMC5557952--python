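"""Model/Results front end over the network, weighting and diffusion layers.

``InfluenceModel`` holds one disease's raw probabilistic interaction network
together with its expression table; ``fit`` carries out the standard
preparation (high-confidence filtering, expression attachment, edge
weighting) and returns an ``InfluenceResults`` object from which cascades are
simulated, coverage rankings computed and a summary printed — mirroring the
model.fit() -> results idiom of statistical modelling libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .diffusion import (
    DEFAULT_N_SIM,
    CascadeRealization,
    CoverageResult,
    RngLike,
    rank_all_nodes,
    simulate_cascade,
)
from .errors import ValidationError
from .network import (
    Dmin,
    ExpressionTable,
    attach_expression,
    filter_high_confidence,
    read_expression_table,
    read_network,
)
from .weights import LpSolution, optimize_edge_weights, rescore_constant


class InfluenceModel:
    """Influence-diffusion model of one disease's miRNA interaction network.

    Parameters
    ----------
    network
        Directed probabilistic miRNA-miRNA network (confidence edge weights).
    expression
        Fold-change table; required for the optimized weighting mode.
    threshold
        High-confidence cut-off applied before weighting (default 0.90).
    """

    def __init__(
        self,
        network: Dmin,
        expression: Optional[ExpressionTable] = None,
        threshold: float = 0.90,
    ) -> None:
        if not 0.0 <= threshold <= 1.0:
            raise ValidationError(f"threshold {threshold} outside [0, 1]")
        self.network = network
        self.expression = expression
        self.threshold = threshold

    @classmethod
    def from_csv(
        cls,
        edges_path: str,
        expression_path: Optional[str] = None,
        disease_id: Optional[str] = None,
        threshold: float = 0.90,
    ) -> "InfluenceModel":
        net = read_network(edges_path, disease_id=disease_id)
        table = (
            read_expression_table(expression_path) if expression_path else None
        )
        return cls(net, table, threshold=threshold)

    def fit(
        self,
        method: str = "optimize",
        constant_weight: float = 0.01,
        tol: float = 1e-8,
        prefiltered: bool = False,
    ) -> "InfluenceResults":
        """Prepare and weight the network.

        ``method`` is ``"optimize"`` (slack-minimizing LP over expression
        scores) or ``"constant"`` (rescore every high-confidence edge to
        ``constant_weight``).  ``prefiltered`` skips the high-confidence
        filter when the input network is already a filtered subnetwork.
        """
        if method not in ("optimize", "constant"):
            raise ValidationError(f"unknown weighting method {method!r}")
        hc = (
            self.network.copy()
            if prefiltered
            else filter_high_confidence(self.network, self.threshold)
        )
        lp: Optional[LpSolution] = None
        if method == "optimize":
            if self.expression is None and not hc.has_expression:
                raise ValidationError(
                    "optimized weighting needs an expression table"
                )
            hce = (
                hc
                if hc.has_expression
                else attach_expression(hc, self.expression)
            )
            weighted, lp = optimize_edge_weights(hce, tol=tol)
        else:
            hce = (
                attach_expression(hc, self.expression)
                if self.expression is not None and not hc.has_expression
                else hc
            )
            weighted = rescore_constant(hce, constant_weight)
        return InfluenceResults(
            model=self,
            network=weighted,
            hc_network=hc,
            lp_solution=lp,
            method=method,
            constant_weight=constant_weight if method == "constant" else None,
        )


@dataclass
class InfluenceResults:
    """Fitted (weighted) network plus diagnostics; entry point for diffusion."""

    model: InfluenceModel
    network: Dmin  # weighted DMIN_HCE
    hc_network: Dmin
    lp_solution: Optional[LpSolution] = None
    method: str = "optimize"
    constant_weight: Optional[float] = None
    _ranking: Optional[CoverageResult] = field(default=None, repr=False)

    @property
    def diagnostics(self) -> dict:
        d: dict = {
            "disease_id": self.network.disease_id,
            "threshold": self.model.threshold,
            "method": self.method,
            "n_nodes": self.network.n,
            "n_edges": self.network.n_edges,
            "removed_nodes": self.network.graph.graph.get("removed_nodes", []),
        }
        if self.lp_solution is not None:
            d["objective"] = self.lp_solution.objective
            d["relaxed_sources"] = self.lp_solution.relaxed_sources
            d["clipped_edges"] = [
                f"{u}->{v}" for u, v in self.lp_solution.clipped_edges
            ]
        if self.constant_weight is not None:
            d["constant_weight"] = self.constant_weight
        return d

    def simulate(
        self, seed_node: str, rng: RngLike = None
    ) -> CascadeRealization:
        """One Independent Cascade realization from ``seed_node``."""
        return simulate_cascade(self.network, seed_node, rng)

    def rank(
        self,
        n_sim: int = DEFAULT_N_SIM,
        rng: RngLike = None,
        exact: bool = False,
    ) -> CoverageResult:
        """Coverage ranking of every node (cached on the results object)."""
        self._ranking = rank_all_nodes(self.network, n_sim=n_sim, rng=rng, exact=exact)
        return self._ranking

    def summary(self, top_k: int = 10) -> str:
        """Human-readable fit summary; includes the top ranking if computed."""
        d = self.diagnostics
        lines = [
            "Influence diffusion results",
            "=" * 45,
            f"Disease:            {d['disease_id']}",
            f"Weighting method:   {d['method']}"
            + (
                f" (constant {d['constant_weight']:g})"
                if "constant_weight" in d
                else ""
            ),
            f"HC threshold:       {d['threshold']:g}",
            f"Nodes / edges:      {d['n_nodes']} / {d['n_edges']}",
        ]
        if self.lp_solution is not None:
            lines += [
                f"LP total |slack|:   {self.lp_solution.objective:.6g}",
                f"Relaxed sources:    {len(self.lp_solution.relaxed_sources)}",
                f"Clipped flows > 1:  {len(self.lp_solution.clipped_edges)}",
            ]
        if d["removed_nodes"]:
            lines.append(f"Nodes w/o expression removed: {len(d['removed_nodes'])}")
        if self._ranking is not None:
            lines.append("-" * 45)
            lines.append(f"Top {top_k} miRNAs by coverage "
                         f"({'exact' if self._ranking.exact else f'{self._ranking.n_sim} MC cycles'}):")
            top = self._ranking.top(top_k)
            lines.append(
                top.to_string(
                    index=False,
                    formatters={
                        "mean_coverage": "{:.4f}".format,
                        "coverage_percentage": "{:.2f}".format,
                    },
                )
            )
        return "\n".join(lines)
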