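"""Cross-disease aggregation of influence over a disease category.

A *category* groups up to five disease networks (e.g. several leukemias).
Two aggregation modes rank its causal miRNAs:

* **Intersection (logical AND)** — keep only the directed edges present in
  every member network; the merged edge weight is the product of the member
  weights (P_new = P_1 x P_2 x ... x P_n), so an interaction must be
  probable in *all* diseases to survive with appreciable weight.  Influence
  is then computed on the merged network and miRNAs with positive mean
  coverage are reported.
* **Cumulative union** — compute each miRNA's coverage percentage separately
  in every member network (each normalized by that network's own node
  count), average the percentages over the diseases where the miRNA occurs,
  and rank; the top 10 are reported by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import DEFAULT_N_SIM, CoverageResult, RngLike, rank_all_nodes
from .errors import ValidationError
from .network import Dmin, read_network

logger = logging.getLogger(__name__)

MAX_CATEGORY_SIZE = 5  # mirrors the published tool's up-to-five-diseases limit
DEFAULT_TOP_K = 10


@dataclass
class CategorySpec:
    """A named group of 1-5 member disease networks and an aggregation mode."""

    category_id: str
    dmins: list[Dmin]
    mode: str = "intersection"  # intersection | cumulative_union

    def __post_init__(self) -> None:
        if self.mode not in ("intersection", "cumulative_union"):
            raise ValidationError(f"unknown category mode {self.mode!r}")
        if not 1 <= len(self.dmins) <= MAX_CATEGORY_SIZE:
            raise ValidationError(
                f"category must contain 1-{MAX_CATEGORY_SIZE} networks, "
                f"got {len(self.dmins)}"
            )


@dataclass
class CategoryResult:
    """Category-level influence ranking."""

    category_id: str
    mode: str
    ranking: pd.DataFrame  # columns: mirna, score, diseases_present
    merged_network: Optional[Dmin] = None  # intersection mode
    per_disease: Optional[pd.DataFrame] = None  # union mode percentage table
    coverage: Optional[CoverageResult] = None

    def to_csv(self, path: str | Path) -> None:
        out = self.ranking.copy()
        out["mode"] = self.mode
        out["diseases_present"] = out["diseases_present"].map(";".join)
        out[["mirna", "score", "mode", "diseases_present"]].to_csv(
            path, index=False, float_format="%.12g"
        )


def intersect_network(spec: CategorySpec) -> Dmin:
    """Merged network: edges in every member, weight = product of weights."""
    if len(spec.dmins) < 2:
        raise ValidationError(
            "intersection needs at least 2 member networks, got "
            f"{len(spec.dmins)}"
        )
    first, *rest = spec.dmins
    merged = Dmin(spec.category_id)
    for u, v, w in first.edges():
        weight = w
        present = True
        for other in rest:
            if other.graph.has_edge(u, v):
                weight *= other.weight(u, v)
            else:
                present = False
                break
        if present:
            merged.add_edge(u, v, weight)
    if merged.n_edges == 0:
        logger.warning(
            "%s: intersection of %d networks is empty",
            spec.category_id, len(spec.dmins),
        )
    return merged


def _diseases_present(spec: CategorySpec, mirna: str) -> list[str]:
    return [d.disease_id for d in spec.dmins if mirna in d]


def intersect_category(
    spec: CategorySpec,
    n_sim: int = DEFAULT_N_SIM,
    rng: RngLike = None,
    exact: bool = False,
) -> CategoryResult:
    """Logical-AND aggregation: influence ranking on the merged network.

    Reports every miRNA with positive mean coverage in the merged network.
    An empty intersection is legal and yields an empty ranking.
    """
    merged = intersect_network(spec)
    empty = pd.DataFrame({"mirna": [], "score": [], "diseases_present": []})
    if merged.n == 0:
        return CategoryResult(spec.category_id, "intersection", empty, merged)
    cov = rank_all_nodes(merged, n_sim=n_sim, rng=rng, exact=exact)
    tab = cov.table[cov.table["mean_coverage"] > 0]
    ranking = pd.DataFrame(
        {
            "mirna": tab["mirna"].to_list(),
            "score": tab["mean_coverage"].to_list(),
            "diseases_present": [
                _diseases_present(spec, m) for m in tab["mirna"]
            ],
        }
    )
    return CategoryResult(
        spec.category_id, "intersection", ranking, merged, coverage=cov
    )


def cumulative_union(
    spec: CategorySpec,
    n_sim: int = DEFAULT_N_SIM,
    rng: RngLike = None,
    top_k: int = DEFAULT_TOP_K,
    exact: bool = False,
) -> CategoryResult:
    """Cumulative-union aggregation: averaged per-disease coverage percentages.

    Each member network's percentages use its own node count; a miRNA's score
    averages only over the diseases containing it (no zero-filling).  The
    top ``top_k`` miRNAs are reported.
    """
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    if isinstance(rng, np.random.Generator):
        master: Optional[int] = int(rng.integers(0, 2**31 - 1))
    else:
        master = rng
    # every member network is ranked under the same master seed, so a
    # single-member category reproduces rank_all_nodes of that network exactly
    frames = []
    for dmin in spec.dmins:
        cov = rank_all_nodes(dmin, n_sim=n_sim, rng=master, exact=exact)
        frames.append(
            pd.DataFrame(
                {
                    "mirna": cov.table["mirna"],
                    "disease": dmin.disease_id,
                    "coverage_percentage": cov.table["coverage_percentage"],
                }
            )
        )
    per_disease = pd.concat(frames, ignore_index=True)
    scores = (
        per_disease.groupby("mirna")["coverage_percentage"].mean().reset_index()
    )
    scores = scores.sort_values(
        ["coverage_percentage", "mirna"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = scores.head(top_k)
    ranking = pd.DataFrame(
        {
            "mirna": top["mirna"].to_list(),
            "score": top["coverage_percentage"].to_list(),
            "diseases_present": [
                _diseases_present(spec, m) for m in top["mirna"]
            ],
        }
    )
    return CategoryResult(
        spec.category_id, "cumulative_union", ranking, per_disease=per_disease
    )


def build_category(
    network_paths: Sequence[str | Path],
    mode: str,
    category_id: str = "category",
    n_sim: int = DEFAULT_N_SIM,
    rng: RngLike = None,
    top_k: int = DEFAULT_TOP_K,
    out_dir: str | Path | None = None,
) -> CategoryResult:
    """End-to-end driver: load member networks, aggregate, optionally write.

    Accepts 1-5 network CSV paths.  With ``out_dir`` set, writes the ranking
    CSV and a provenance JSON (inputs, parameters, seed) there.
    """
    if not 1 <= len(network_paths) <= MAX_CATEGORY_SIZE:
        raise ValidationError(
            f"a category combines 1-{MAX_CATEGORY_SIZE} disease networks, "
            f"got {len(network_paths)}"
        )
    dmins = [read_network(p) for p in network_paths]
    spec = CategorySpec(category_id=category_id, dmins=dmins, mode=mode)
    if mode == "intersection":
        result = intersect_category(spec, n_sim=n_sim, rng=rng)
    else:
        result = cumulative_union(spec, n_sim=n_sim, rng=rng, top_k=top_k)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_dir / f"{category_id}_ranking.csv")
        provenance = {
            "category_id": category_id,
            "mode": mode,
            "inputs": [str(p) for p in network_paths],
            "n_sim": n_sim,
            "seed": rng if isinstance(rng, int) else None,
            "top_k": top_k,
        }
        (out_dir / f"{category_id}_provenance.json").write_text(
            json.dumps(provenance, indent=2) + "\n", encoding="utf-8"
        )
    return result
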