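"""Domain types and I/O for miRNA expression tables and disease networks.

A *DMIN* (disease-specific miRNA interaction network) is a directed graph of
predicted miRNA-miRNA regulatory edges for one disease, each edge carrying a
probability-like weight in [0, 1].  A node may additionally carry an
*expression score* ``e_i``: the magnitude of its log2 fold change in the
disease, aggregated over studies.  The high-confidence subnetwork (edges with
confidence >= 0.90) is called the DMIN_HC; once expression scores are attached
it is the DMIN_HCE that downstream weighting and diffusion operate on.

miRNA identifiers are opaque, case-sensitive strings; no normalisation of
naming variants is attempted.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import FormatError, NotFoundError, ValidationError

logger = logging.getLogger(__name__)

#: edge-weight sentinel used after high-confidence filtering discards the
#: original probabilities (deterministic full propagation until re-weighted)
DISCARDED_WEIGHT = 1.0


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """One fold-change observation for a (miRNA, disease) pair."""

    mirna_id: str
    disease_id: str
    fold_change: float
    regulation: str = "unspecified"  # up | down | unspecified
    study_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.fold_change > 0 and math.isfinite(self.fold_change)):
            raise ValidationError(
                f"fold_change must be a positive finite real, got "
                f"{self.fold_change!r} for ({self.mirna_id}, {self.disease_id})"
            )
        if self.regulation not in ("up", "down", "unspecified"):
            raise ValidationError(f"unknown regulation {self.regulation!r}")


class ExpressionTable:
    """Fold-change observations, possibly replicated across studies.

    (miRNA, disease) pairs may repeat: multiple studies can report the same
    pair, and their scores are averaged by :meth:`aggregate`.
    """

    def __init__(self, records: Iterable[ExpressionRecord] = ()) -> None:
        self.records: list[ExpressionRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExpressionRecord]:
        return iter(self.records)

    def matching(self, mirna_id: str, disease_id: str) -> list[ExpressionRecord]:
        return [
            r
            for r in self.records
            if r.mirna_id == mirna_id and r.disease_id == disease_id
        ]

    def mirnas(self, disease_id: str) -> set[str]:
        return {r.mirna_id for r in self.records if r.disease_id == disease_id}

    def aggregate(self, mirna_id: str, disease_id: str) -> float:
        return aggregate_expression(self, mirna_id, disease_id)

    def aggregate_signed(self, mirna_id: str, disease_id: str) -> float:
        """Mean of signed log2 fold changes (metadata; not used by the LP)."""
        recs = self.matching(mirna_id, disease_id)
        if not recs:
            raise NotFoundError(
                f"no expression record for ({mirna_id}, {disease_id})"
            )
        return sum(math.log2(r.fold_change) for r in recs) / len(recs)


def aggregate_expression(
    table: ExpressionTable, mirna_id: str, disease_id: str
) -> float:
    """Aggregated expression score: mean of |log2(fold change)| over studies.

    Fold changes are converted to log2 before averaging; the absolute value
    makes up- and down-regulation contribute identically, since a miRNA is
    considered an influence driver regardless of regulation direction.
    The signed mean is available via :meth:`ExpressionTable.aggregate_signed`.
    """
    recs = table.matching(mirna_id, disease_id)
    if not recs:
        raise NotFoundError(f"no expression record for ({mirna_id}, {disease_id})")
    return sum(abs(math.log2(r.fold_change)) for r in recs) / len(recs)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read an expression CSV: header ``mirna,disease,fold_change[,regulation][,study]``."""
    path = Path(path)
    records: list[ExpressionRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        for col in ("mirna", "disease", "fold_change"):
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            raw = row["fold_change"]
            try:
                fc = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {i}: fold_change {raw!r} is not numeric"
                ) from None
            if not fc > 0:
                raise ValidationError(
                    f"{path}: row {i}: fold_change must be > 0, got {fc}"
                )
            records.append(
                ExpressionRecord(
                    mirna_id=row["mirna"],
                    disease_id=row["disease"],
                    fold_change=fc,
                    regulation=(row.get("regulation") or "unspecified").strip()
                    or "unspecified",
                    study_id=(row.get("study") or None),
                )
            )
    return ExpressionTable(records)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mirna", "disease", "fold_change", "regulation", "study"])
        for r in table:
            writer.writerow(
                [r.mirna_id, r.disease_id, repr(float(r.fold_change)), r.regulation,
                 r.study_id or ""]
            )


# ---------------------------------------------------------------------------
# Directed disease networks
# ---------------------------------------------------------------------------

class Dmin:
    """Directed probabilistic miRNA-miRNA interaction network for one disease.

    Thin wrapper around :class:`networkx.DiGraph` enforcing the domain
    invariants: no self-loops, edge weights in [0, 1], every edge endpoint a
    node.  Node attribute ``expression`` (e_i >= 0) is absent until attached;
    edge attribute ``weight`` is the confidence probability or, after
    optimization, the influence flow X_ij clipped to 1.
    """

    def __init__(self, disease_id: str, graph: Optional[nx.DiGraph] = None) -> None:
        self.disease_id = disease_id
        self.graph = graph if graph is not None else nx.DiGraph()
        self.graph.graph.setdefault("weights_discarded", False)

    # -- construction ------------------------------------------------------

    def add_node(self, mirna_id: str, expression: Optional[float] = None,
                 **attrs: object) -> None:
        if expression is not None:
            if not (expression >= 0 and math.isfinite(expression)):
                raise ValidationError(
                    f"expression score must be finite and >= 0, got {expression}"
                )
            attrs["expression"] = expression
        self.graph.add_node(mirna_id, **attrs)

    def add_edge(self, source: str, target: str, weight: float) -> None:
        """Add a directed edge; duplicate edges keep the maximum weight."""
        if source == target:
            raise ValidationError(f"self-loop {source}->{target} not allowed")
        _check_weight(weight, f"{source}->{target}")
        if self.graph.has_edge(source, target):
            old = self.graph[source][target]["weight"]
            if weight < old:
                logger.warning(
                    "duplicate edge %s->%s: keeping max weight %g over %g",
                    source, target, old, weight,
                )
                return
            logger.warning(
                "duplicate edge %s->%s: keeping max weight %g over %g",
                source, target, weight, old,
            )
        self.graph.add_edge(source, target, weight=weight)

    def copy(self) -> "Dmin":
        return Dmin(self.disease_id, self.graph.copy())

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def weight(self, source: str, target: str) -> float:
        return self.graph[source][target]["weight"]

    def expression(self, mirna_id: str) -> float:
        if mirna_id not in self.graph:
            raise NotFoundError(f"node {mirna_id!r} not in network")
        try:
            return self.graph.nodes[mirna_id]["expression"]
        except KeyError:
            raise NotFoundError(
                f"node {mirna_id!r} has no expression score attached"
            ) from None

    @property
    def has_expression(self) -> bool:
        return any("expression" in d for _, d in self.graph.nodes(data=True))

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dmin):
            return NotImplemented
        if self.disease_id != other.disease_id:
            return False
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        mine, theirs = self.edges(), other.edges()
        if len(mine) != len(theirs):
            return False
        for (u1, v1, w1), (u2, v2, w2) in zip(mine, theirs):
            if (u1, v1) != (u2, v2) or not math.isclose(
                w1, w2, rel_tol=1e-12, abs_tol=1e-15
            ):
                return False
        for node in self.graph.nodes:
            e1 = self.graph.nodes[node].get("expression")
            e2 = other.graph.nodes[node].get("expression")
            if (e1 is None) != (e2 is None):
                return False
            if e1 is not None and not math.isclose(
                e1, e2, rel_tol=1e-12, abs_tol=1e-15
            ):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"Dmin({self.disease_id!r}, n={self.n}, edges={self.n_edges}, "
            f"expression={'yes' if self.has_expression else 'no'})"
        )

    def validate(self) -> None:
        """Re-check all structural invariants (used after deserialization)."""
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop {u}->{v}")
            _check_weight(d.get("weight"), f"{u}->{v}")


def _check_weight(weight: object, label: str) -> None:
    if not isinstance(weight, (int, float)) or not math.isfinite(weight):
        raise ValidationError(f"edge {label}: weight {weight!r} is not a finite real")
    if not 0.0 <= weight <= 1.0:
        raise ValidationError(f"edge {label}: weight {weight} outside [0, 1]")


# ---------------------------------------------------------------------------
# DMIN_HC / DMIN_HCE construction
# ---------------------------------------------------------------------------

def filter_high_confidence(network: Dmin, threshold: float = 0.90) -> Dmin:
    """High-confidence subnetwork: edges with weight >= threshold (inclusive).

    Original confidence probabilities are retained as edge metadata
    (``confidence``) but flagged discarded; the working ``weight`` becomes the
    1.0 sentinel until a weighting mode overwrites it.  Nodes left without any
    incident edge are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    out = Dmin(network.disease_id)
    for u, v, d in network.graph.edges(data=True):
        conf = d.get("confidence", d["weight"])
        if conf >= threshold:
            out.graph.add_edge(u, v, weight=DISCARDED_WEIGHT, confidence=conf)
    # carry over node attributes for surviving nodes
    for node in out.graph.nodes:
        out.graph.nodes[node].update(network.graph.nodes[node])
    out.graph.graph["weights_discarded"] = True
    out.graph.graph["hc_threshold"] = threshold
    if out.n == 0 and network.n > 0:
        logger.warning(
            "%s: no edge reaches confidence %g; high-confidence network is empty",
            network.disease_id, threshold,
        )
    return out


def attach_expression(network: Dmin, table: ExpressionTable) -> Dmin:
    """Annotate every node with its aggregated expression score (DMIN_HCE).

    Nodes without any expression record for the network's disease are removed
    with a logged warning rather than imputed: the downstream flow model is
    undefined without e_i, and inventing a score would fabricate data.
    """
    if network.has_expression:
        raise ValidationError(
            f"{network.disease_id}: network already carries expression scores"
        )
    out = network.copy()
    missing = [
        node
        for node in out.graph.nodes
        if not table.matching(node, network.disease_id)
    ]
    for node in missing:
        out.graph.remove_node(node)
    if missing:
        logger.warning(
            "%s: removed %d node(s) lacking expression records: %s",
            network.disease_id, len(missing), ", ".join(sorted(missing)),
        )
    for node in out.graph.nodes:
        out.graph.nodes[node]["expression"] = aggregate_expression(
            table, node, network.disease_id
        )
        out.graph.nodes[node]["signed_log2"] = table.aggregate_signed(
            node, network.disease_id
        )
    out.graph.graph["removed_nodes"] = sorted(missing)
    return out


# ---------------------------------------------------------------------------
# Network I/O (edge CSV + optional node annotation CSV)
# ---------------------------------------------------------------------------

def _nodes_path(edges_path: Path) -> Path:
    return edges_path.with_suffix(".nodes.csv")


def write_network(
    network: Dmin,
    path: str | Path,
    nodes_path: str | Path | None = None,
) -> None:
    """Write the edge list (``source,target,weight``) and a companion node
    annotation CSV (``mirna,expression``; expression blank where absent).

    The round trip through :func:`read_network` is lossless to 12 significant
    digits on weights and expression scores.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for u, v, w in network.edges():
            writer.writerow([u, v, repr(float(w))])
    # the node annotation CSV also preserves isolated nodes, which the edge
    # list alone cannot represent
    npath = Path(nodes_path) if nodes_path is not None else _nodes_path(path)
    with npath.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mirna", "expression"])
        for node in network.nodes():
            expr = network.graph.nodes[node].get("expression")
            writer.writerow([node, "" if expr is None else repr(float(expr))])


def read_network(
    path: str | Path,
    disease_id: str | None = None,
    nodes_path: str | Path | None = None,
) -> Dmin:
    """Read a network edge CSV, plus the node annotation CSV if it exists.

    ``disease_id`` defaults to the file stem.
    """
    path = Path(path)
    if disease_id is None:
        disease_id = path.stem
    net = Dmin(disease_id)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["source", "target", "weight"]:
            raise FormatError(
                f"{path}: expected header 'source,target,weight', got {header!r}"
            )
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise FormatError(f"{path}: line {i}: expected 3 fields, got {len(row)}")
            u, v, raw = row[0], row[1], row[2]
            try:
                w = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: line {i}: weight {raw!r} is not numeric"
                ) from None
            try:
                net.add_edge(u, v, w)
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {i}: {exc}") from None
    npath = Path(nodes_path) if nodes_path is not None else _nodes_path(path)
    if npath.exists():
        with npath.open(newline="", encoding="utf-8") as fh:
            nreader = csv.DictReader(fh)
            if nreader.fieldnames is None or "mirna" not in nreader.fieldnames:
                raise FormatError(f"{npath}: expected header 'mirna,expression'")
            for i, row in enumerate(nreader, start=2):
                node = row["mirna"]
                raw = (row.get("expression") or "").strip()
                if raw:
                    try:
                        expr = float(raw)
                    except ValueError:
                        raise FormatError(
                            f"{npath}: line {i}: expression {raw!r} is not numeric"
                        ) from None
                    net.add_node(node, expression=expr)
                else:
                    net.graph.add_node(node)
    net.validate()
    return net
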