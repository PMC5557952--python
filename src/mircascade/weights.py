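"""Edge weighting for the annotated disease network (DMIN_HCE).

Two modes produce the influence weights the cascade model consumes:

* **Optimized** — a linear program distributes each node's expression score
  e_i over its edges as flows X_ij.  The incoming flow of every regulated
  node must reproduce its expression score exactly
  (sum_j e_j * X_ji = e_i), while the outgoing side is relaxed by a per-node
  slack (sum_j e_i * X_ij + s_i = e_i); the total absolute slack
  sum_i |s_i| is minimized.  The optimum is the flow assignment that explains
  the observed expression pattern with the least unexplained "leakage".
* **Constant** — every surviving edge is rescored to one fixed probability
  (default 0.01), which isolates the topological pressure points of a dense
  network from its (noisy) confidence scores.

The |s_i| objective is linearized exactly via s_i = s+_i - s-_i with both
parts nonnegative.  Flow variables exist only for edges present in the
network; the incoming equality is dropped for in-degree-0 nodes, which are
treated as exogenous drivers (the equality 0 = e_i would otherwise make any
expressed source node infeasible).  Solved with scipy's HiGHS backend, which
is deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleError, ValidationError
from .network import Dmin

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class LpSolution:
    """Solved flows and slacks of the edge-weight linear program."""

    flows: dict[Edge, float]
    slacks: dict[str, float]
    objective: float
    status: str  # optimal | infeasible
    relaxed_sources: list[str] = field(default_factory=list)
    clipped_edges: list[Edge] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "objective": self.objective,
            "slacks": dict(sorted(self.slacks.items())),
            "flows": {f"{u}->{v}": x for (u, v), x in sorted(self.flows.items())},
            "relaxed_sources": self.relaxed_sources,
            "clipped_edges": [f"{u}->{v}" for u, v in self.clipped_edges],
        }


def optimize_edge_weights(
    network: Dmin, tol: float = 1e-8
) -> tuple[Dmin, LpSolution]:
    """Solve the slack-minimizing flow LP and return the re-weighted network.

    Every node must carry an expression score e_i >= 0 and the network must
    have at least one edge.  Returned edge weights are min(X_ij, 1): the LP
    does not bound flows above, but the cascade model needs probabilities, so
    flows above 1 are clipped with a logged count.

    Raises
    ------
    InfeasibleError
        If no flow assignment satisfies the incoming equalities, e.g. a node
        with e_i > 0 whose in-neighbours all have zero expression.
    """
    nodes = network.nodes()
    if not nodes:
        raise ValidationError("cannot optimize an empty network")
    edges = [(u, v) for u, v, _ in network.edges()]
    if not edges:
        raise ValidationError(
            f"{network.disease_id}: network has no edges to optimize"
        )
    e = {i: network.expression(i) for i in nodes}  # raises if missing

    # analytically forced infeasibility: expressed node fed only by silent ones
    for i in nodes:
        preds = list(network.graph.predecessors(i))
        if preds and e[i] > 0 and all(e[j] == 0 for j in preds):
            raise InfeasibleError(
                f"node {i!r}: incoming constraint requires e={e[i]:g} but all "
                f"in-neighbours have zero expression"
            )

    zero_nodes = sorted(i for i in nodes if e[i] == 0)
    if zero_nodes:
        logger.warning(
            "%s: %d node(s) with zero expression score: %s",
            network.disease_id, len(zero_nodes), ", ".join(zero_nodes),
        )

    n, m = len(nodes), len(edges)
    node_ix = {node: k for k, node in enumerate(nodes)}
    edge_ix = {edge: k for k, edge in enumerate(edges)}
    # variable layout: [X_e (m)] [s+ (n)] [s- (n)]
    nvar = m + 2 * n
    cost = np.zeros(nvar)
    cost[m:] = 1.0

    rows, cols, vals, rhs = [], [], [], []
    row = 0
    sources = []
    for i in nodes:
        preds = list(network.graph.predecessors(i))
        if not preds:
            sources.append(i)
            continue  # in-degree-0: exogenous driver, equality dropped
        for j in preds:
            rows.append(row)
            cols.append(edge_ix[(j, i)])
            vals.append(e[j])
        rhs.append(e[i])
        row += 1
    for i in nodes:
        k = node_ix[i]
        for j in network.graph.successors(i):
            rows.append(row)
            cols.append(edge_ix[(i, j)])
            vals.append(e[i])
        rows.extend([row, row])
        cols.extend([m + k, m + n + k])
        vals.extend([1.0, -1.0])
        rhs.append(e[i])
        row += 1

    from scipy.sparse import coo_matrix

    a_eq = coo_matrix((vals, (rows, cols)), shape=(row, nvar)).tocsr()
    res = linprog(
        cost,
        A_eq=a_eq,
        b_eq=np.asarray(rhs),
        bounds=(0, None),
        method="highs",
        options={
            "primal_feasibility_tolerance": tol,
            "dual_feasibility_tolerance": tol,
        },
    )
    if res.status == 2:
        raise InfeasibleError(
            f"{network.disease_id}: edge-weight LP infeasible: {res.message}"
        )
    if not res.success:
        raise InfeasibleError(
            f"{network.disease_id}: LP solver failed (status {res.status}): "
            f"{res.message}"
        )

    x = res.x
    flows = {edge: float(x[edge_ix[edge]]) for edge in edges}
    slacks = {
        i: float(x[m + node_ix[i]] - x[m + n + node_ix[i]]) for i in nodes
    }
    objective = float(sum(abs(s) for s in slacks.values()))

    clipped = sorted(edge for edge, f in flows.items() if f > 1.0)
    if clipped:
        logger.warning(
            "%s: clipped %d flow(s) above 1 to unit probability",
            network.disease_id, len(clipped),
        )
    if sources:
        logger.info(
            "%s: incoming equality relaxed for %d source node(s): %s",
            network.disease_id, len(sources), ", ".join(sources),
        )

    out = network.copy()
    for (u, v), f in flows.items():
        out.graph[u][v]["weight"] = min(max(f, 0.0), 1.0)
    out.graph.graph["weights_discarded"] = False
    out.graph.graph["weight_mode"] = "optimize"

    sol = LpSolution(
        flows=flows,
        slacks=slacks,
        objective=objective,
        status="optimal",
        relaxed_sources=sources,
        clipped_edges=clipped,
    )
    return out, sol


def rescore_constant(network: Dmin, weight: float = 0.01) -> Dmin:
    """Replace every edge weight with one constant in (0, 1]; topology unchanged."""
    if not (isinstance(weight, (int, float)) and 0.0 < weight <= 1.0):
        raise ValidationError(f"constant weight must be in (0, 1], got {weight!r}")
    out = network.copy()
    for u, v in out.graph.edges:
        out.graph[u][v]["weight"] = float(weight)
    out.graph.graph["weights_discarded"] = False
    out.graph.graph["weight_mode"] = f"constant({weight:g})"
    return out


def verify_lp_solution(
    network: Dmin, sol: LpSolution, tol: float = 1e-6
) -> dict:
    """Independently check an LP solution against the flow constraints.

    Returns a report with the maximum absolute residual of each constraint
    family (incoming equalities at regulated nodes, outgoing equalities,
    flow nonnegativity) and a ``passed`` flag.  Flows absent from
    ``sol.flows`` count as zero, so an empty map flags every constraint with
    positive expression on it.
    """
    if sol.status != "optimal":
        raise ValidationError(f"cannot verify a solution with status {sol.status!r}")
    e = {i: network.expression(i) for i in network.nodes()}

    def flow(u: str, v: str) -> float:
        return sol.flows.get((u, v), 0.0)

    incoming = 0.0
    for i in network.nodes():
        preds = list(network.graph.predecessors(i))
        if not preds:
            continue
        lhs = sum(e[j] * flow(j, i) for j in preds)
        incoming = max(incoming, abs(lhs - e[i]))
    outgoing = 0.0
    for i in network.nodes():
        lhs = sum(e[i] * flow(i, j) for j in network.graph.successors(i))
        outgoing = max(outgoing, abs(lhs + sol.slacks.get(i, 0.0) - e[i]))
    negativity = max(
        (max(0.0, -f) for f in sol.flows.values()), default=0.0
    )
    obj_residual = abs(
        sol.objective - sum(abs(s) for s in sol.slacks.values())
    )
    report = {
        "max_incoming_residual": incoming,
        "max_outgoing_residual": outgoing,
        "max_negativity": negativity,
        "objective_residual": obj_residual,
        "tol": tol,
        "passed": max(incoming, outgoing, negativity, obj_residual) <= tol,
    }
    return report
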