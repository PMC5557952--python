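# mircascade

Influence-diffusion analysis of disease-specific miRNA–miRNA interaction
networks (DMINs): rank the miRNAs most likely to *drive* a disease's
regulatory state by how far a cascade of activations seeded at each miRNA is
expected to spread.

## Who this is for

Systems-biology researchers holding (a) a directed, probabilistic
miRNA–miRNA interaction network for one or more diseases (edge weights are
confidence probabilities, e.g. from consensus network inference) and (b) a
table of miRNA fold changes in those diseases, who want a reproducible,
scriptable reimplementation of the influence-diffusion ranking — including
cross-disease category analysis — without a web front-end.

## The model

**Network preparation.** For each disease, edges with confidence ≥ 0.90 form
the high-confidence subnetwork DMIN_HC. Each surviving node i is annotated
with an expression score e_i = mean |log₂ fold-change| over the studies
reporting it (magnitude, because a miRNA is treated as an influence driver
whether up- or down-regulated). Nodes without expression records are removed,
not imputed.

**Edge weighting.** Two modes produce the influence probabilities X_ij:

- *Optimized*: solve the linear program

  ```
  minimize    Σᵢ |sᵢ|
  subject to  Σⱼ eⱼ·Xⱼᵢ = eᵢ          (incoming flow, per regulated node)
              Σⱼ eᵢ·Xᵢⱼ + sᵢ = eᵢ     (outgoing flow, slack sᵢ free)
              Xᵢⱼ ≥ 0, i ≠ j
  ```

  Each node's expression must be exactly explained by its incoming weighted
  flow; the outgoing side is relaxed by a per-node slack, and total absolute
  slack is minimized. Source nodes (in-degree 0) are treated as exogenous
  drivers. Flows above 1 are clipped to unit probability for the simulation
  stage.
- *Constant*: rescore every edge to a fixed small probability (default 0.01),
  isolating the purely topological pressure points of dense networks.

**Influence (coverage).** Under the Independent Cascade model, each newly
activated node gets one biased coin toss per out-edge (bias = edge weight) to
activate its neighbour. COV(u) is the expected number of nodes (excluding u)
activated by a cascade seeded at u, estimated over 10,000 Monte-Carlo cycles
and expressed as a percentage of the network's node count. An exact
live-edge enumeration oracle is available for networks with ≤ 20 edges.

**Disease categories.** Up to five related diseases can be aggregated:

- *Intersection (logical AND)*: keep edges present in every member network
  with weight P_new = P₁ × P₂ × … × Pₙ, then rank on the merged network;
- *Cumulative union*: average each miRNA's per-disease coverage percentages
  over the diseases containing it and report the top 10.

## Worked example

```python
import mircascade as mc

net = mc.Dmin("dz")
net.add_edge("miR-a", "miR-b", 0.95)
net.add_edge("miR-b", "miR-c", 0.92)
net.add_edge("miR-c", "miR-a", 0.50)   # below the 0.90 cut-off
table = mc.ExpressionTable([
    mc.ExpressionRecord("miR-a", "dz", 4.0),
    mc.ExpressionRecord("miR-b", "dz", 2.0),
    mc.ExpressionRecord("miR-b", "dz", 2.0),   # replicate study
    mc.ExpressionRecord("miR-c", "dz", 0.5),   # down-regulated
])
results = mc.InfluenceModel(net, table, threshold=0.90).fit(method="optimize")
results.rank(n_sim=10_000, rng=1)
print(results.summary(top_k=3))
```

```
Influence diffusion results
=============================================
Disease:            dz
Weighting method:   optimize
HC threshold:       0.9
Nodes / edges:      3 / 2
LP total |slack|:   2
Relaxed sources:    1
Clipped flows > 1:  0
---------------------------------------------
Top 3 miRNAs by coverage (10000 MC cycles):
mirna mean_coverage coverage_percentage  rank
miR-a        1.0054               33.51     1
miR-b        1.0000               33.33     2
miR-c        0.0000                0.00     3
```

The low-confidence edge miR-c→miR-a is filtered out, leaving the chain
miR-a→miR-b→miR-c with expression scores (2, 1, 1) = mean |log₂ fold-change|.
The LP forces flows X = (0.5, 1.0) from the incoming equalities; miR-a is a
relaxed source and the terminal node's unexplained expression contributes
the total slack of 2. Seeded at miR-a, the cascade activates miR-b with
probability 0.5 and then miR-c with probability 1, so COV(miR-a) ≈ 1.0 —
the Monte-Carlo estimate 1.0054 sits within sampling error of the exact
value 1.0 — covering 33.5% of the 3-node network and ranking first
(ties break lexicographically).

On the bundled five-node toy network the exact live-edge expectation and the
Monte-Carlo estimate agree to three decimals:

```python
toy = mc.toy_cascade_fixture()
mc.exact_expected_coverage(toy, "n1")          # 2.4125
mc.compute_coverage(toy, "n1", n_sim=10_000, rng=1)   # 2.4127
```

The same pipeline is scriptable from the shell:

```
mircascade fixtures --preset toy --out toy.csv
mircascade run --edges toy.csv --mode constant --nsim 10000 --seed 1 --out out/
mircascade category --mode union --inputs d1.csv --inputs d2.csv --seed 1 --out cat/
```

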