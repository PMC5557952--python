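# Methods

This note documents the modelling choices, numerical conventions and known
limitations of mircascade. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Expression scores

Each node's expression score is e_i = mean over studies of |log₂ FC|, where
FC > 0 is the reported fold change of the miRNA in the disease relative to
control.

- **Log before mean.** Conversion to log₂ happens per record, before
  averaging; this equals the log of the geometric mean of the fold changes
  and treats up- and down-regulation symmetrically (a 4× increase and a 4×
  decrease both score 2). Averaging raw fold changes instead would bias the
  score toward up-regulation.
- **Magnitude policy.** The flow model needs e_i ≥ 0, and a miRNA is taken
  to drive influence regardless of regulation direction, so the absolute
  value is applied per record before the mean. The signed mean is retained
  as node metadata (`signed_log2`) for inspection but enters no computation.
  Note the two orders differ: a pair {0.25, 4} scores 2 under
  abs-then-mean, 0 under mean-then-abs; the former is the intended
  behaviour here, since opposing studies should not silence a miRNA.
- Nodes with no expression record are **removed**, not imputed: the LP is
  undefined without e_i and imputation would fabricate data. Removals are
  logged and recorded in run provenance.

## High-confidence filtering

The cut-off (default 0.90, boundary inclusive) is applied to the edge
*confidence* probabilities. After filtering, confidences are kept as edge
metadata but flagged discarded; the working weight becomes a sentinel 1.0
until a weighting mode overwrites it, making it impossible to accidentally
simulate on stale confidence values while keeping the graph well-formed.
Duplicate directed edges in an input file keep the maximum probability
(conservative toward retention at the cut-off; logged).

## The edge-weight linear program

Variables are flows X_ij ≥ 0 on *existing* edges only (real DMINs are
sparse; absent edges carry no influence), plus a slack pair per node.

- **|s| linearization**: s_i = s⁺_i − s⁻_i with s⁺, s⁻ ≥ 0 and objective
  Σ(s⁺+s⁻) — the standard exact reformulation; at any optimum at most one
  of the pair is nonzero.
- **Source relaxation**: the incoming equality Σ_j e_j X_ji = e_i is
  enforced only for nodes with in-degree ≥ 1. For a source node it would
  read 0 = e_i and make every expressed source infeasible; sources are
  instead treated as exogenous drivers. The relaxed node list is reported in
  the solution and in provenance.
- **Infeasibility**: a node with e_i > 0 fed only by zero-expression parents
  is detected before solving and reported by name; any residual solver
  infeasibility raises with the solver message.
- **Zero-expression nodes** are legal: their outgoing constraint forces
  s_i = 0 and their out-edges contribute nothing (logged).
- **Clipping**: the LP does not bound X above, but the cascade stage needs
  probabilities, so exported weights are min(X, 1) with the clipped edge
  list logged and preserved in the solution object. The unclipped flows
  remain available in `LpSolution.flows`.
- **Solver**: scipy's HiGHS backend, primal/dual feasibility tolerance 1e-8,
  single-threaded and deterministic for a fixed input. Degenerate instances
  can have multiple optimal flow vectors; the contract is the verification
  report (`verify_lp_solution`, residual tolerance 1e-6), not the exact X
  vector. The independent checker recomputes both constraint families from
  the stored flows without consulting the solver.

## Independent Cascade simulation

- **Semantics**: one attempt per edge per realization; an already-active
  target is never re-attempted. The seed is excluded from its own coverage
  count (a seed influencing three nodes in a five-node graph scores 3).
- **Percentage denominator**: the full node count n, so percentage =
  COV/n × 100; the alternative n−1 was rejected to keep "influences 70% of
  the nodes" literally true.
- **Activation order**: FIFO frontier with out-neighbours visited in sorted
  order. Because every edge fires independently, the final activated set is
  order-independent; only the attempt trace depends on order.
- **Estimator**: per-node means over n_sim = 10,000 replicates by default
  (standard error ≈ 0.005 on a Bernoulli-like unit coverage). Replicates
  are sampled via the live-edge representation — every edge's state is drawn
  up front and coverage is the live-reachability count — which is
  distributionally identical to sequential coin tosses and vectorizes over
  replicates. Networks above 128 nodes fall back to a per-replicate
  traversal to avoid large dense adjacency batches; both paths are seeded
  and deterministic.
- **RNG discipline**: one master seed; each (node, replicate-block) uses a
  substream keyed by the node's position in sorted id order, so per-node
  coverage is independent of evaluation order and bit-reproducible.
- **Exact oracle**: live-edge enumeration over all 2^|E| configurations,
  guarded at 20 edges (~1M configurations, seconds on one CPU; enumeration
  is batched and the per-batch transitive closure is computed by repeated
  boolean matrix squaring). The oracle is an independent code path used to
  validate the Monte-Carlo estimator.
- **Ranking ties** break lexicographically by miRNA id so ranked output is
  identical across runs and platforms.

## Category aggregation

- **Intersection** matches edges by exact (source, target) id equality; the
  merged weight is the product of member weights, hence never above their
  minimum, and the merge is order-independent. The ranking reports all
  nodes with positive mean coverage on the merged network (the least
  arbitrary cutoff for a short unranked list). An empty intersection is
  legal and yields an empty ranking with a warning.
- **Cumulative union** normalizes each member's coverage by that network's
  own node count before averaging, and averages only over diseases
  containing the miRNA (no zero-filling), then reports the top 10 by
  default. Every member is ranked under the same master seed, so a
  single-member category reproduces `rank_all_nodes` of that network
  exactly.
- Categories are capped at five member networks, mirroring the published
  tool's limit; the cap is a named constant.

## Synthetic data

The fixture module generates all test inputs; no downloads are needed.

- **Toy cascade network**: five nodes; the two printed weights are 0.5
  (1→2) and 0.9 (1→3); the remaining three edges default to 0.5 and are
  overridable. Tests that need the depicted realization force the coin-toss
  outcomes directly rather than relying on those defaults.
- **Random DMINs**: directed Erdős–Rényi at a configurable density with
  uniform, constant or high-confidence (0.9–1.0) weights and log-normal
  (μ=0, σ=1) or fixed expression scores. The log-normal default makes up-
  and down-regulation symmetric on the log₂ scale, emulating the mixed
  regulation directions of curated fold-change databases.
- **Planted influencer**: one hub with `hub_out_degree` out-edges at a high
  weight (default 0.9) over sparse background edges at a low weight
  (default 0.05). The background *density* (0.05 of ordered non-hub pairs)
  is a package choice — sparse enough that the hub's expected spread
  dominates by construction. Recovery tests use 20 seeded runs at 1,000
  Monte-Carlo cycles each; the hub's expected coverage (~13.5) exceeds any
  background node's by an order of magnitude, so this simulation size is
  ample.
- **Expression tables**: log-normal fold changes with a configurable
  fraction of (miRNA, disease) pairs replicated across pseudo-studies,
  exercising the averaging path.

What the synthetic generators do **not** emulate: the degree heterogeneity,
motif structure and confidence-score correlations of inferred biological
networks, batch effects or study heterogeneity beyond i.i.d. replicates, and
any temporal structure. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not biological validity of
rankings on real data.

## Problem sizes and verification scale

Statistical checks run at sizes chosen to make their error bounds sharp yet
cheap: oracle-vs-Monte-Carlo agreement uses 200 random graphs with ≤ 6 nodes
and ≤ 10 edges at 10,000 cycles per node (each comparison bounded by 4
standard errors of the per-node sample mean); LP verification uses 100
random annotated graphs of 3–7 nodes; the intersection product rule is
checked over 1,000 random weight tuples. The vectorized live-edge kernel
makes the full suite run in seconds.

## Known limitations

- Edge weights are static: the model does not capture time-varying
  influence or kinetics.
- The LP explains expression as a single steady flow; alternative optima
  exist on degenerate topologies (only the slack objective and constraint
  residuals are unique).
- Influence maximization (optimal seed *sets*) and the Linear Threshold
  diffusion model are out of scope.
- miRNA identifiers are matched as opaque strings; name-variant
  normalisation must happen upstream.
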