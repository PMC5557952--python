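"""Edge-weight LP, constant rescoring, and the independent constraint checker."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mircascade import (
    Dmin,
    FixtureConfig,
    InfeasibleError,
    LpSolution,
    ValidationError,
    filter_high_confidence,
    generate_random_dmin,
    optimize_edge_weights,
    rescore_constant,
    verify_lp_solution,
)


def test_two_node_hand_solution(two_node_lp):
    weighted, sol = optimize_edge_weights(two_node_lp)
    assert sol.flows[("A", "B")] == pytest.approx(1.0, abs=1e-6)
    assert sol.slacks["A"] == pytest.approx(0.0, abs=1e-6)
    assert sol.slacks["B"] == pytest.approx(2.0, abs=1e-6)
    assert sol.objective == pytest.approx(2.0, abs=1e-6)
    assert weighted.weight("A", "B") == pytest.approx(1.0, abs=1e-6)


def test_chain_hand_solution(chain_lp):
    _, sol = optimize_edge_weights(chain_lp)
    assert sol.flows[("A", "B")] == pytest.approx(1.0, abs=1e-6)
    assert sol.flows[("B", "C")] == pytest.approx(1.0, abs=1e-6)
    assert [sol.slacks[x] for x in "ABC"] == pytest.approx([0, 0, 1], abs=1e-6)
    assert sol.objective == pytest.approx(1.0, abs=1e-6)


def test_silent_upstream_is_infeasible():
    net = Dmin("d")
    net.add_node("A", expression=0.0)
    net.add_node("B", expression=3.0)
    net.add_edge("A", "B", 1.0)
    with pytest.raises(InfeasibleError, match="B"):
        optimize_edge_weights(net)


def test_missing_expression_is_a_precondition_error(two_node_lp):
    two_node_lp.graph.add_node("C")
    two_node_lp.graph.add_edge("A", "C", weight=0.5)
    with pytest.raises(Exception, match="expression"):
        optimize_edge_weights(two_node_lp)


def test_source_nodes_are_relaxed_not_infeasible(two_node_lp):
    # A has in-degree 0 and positive expression; the incoming equality is
    # dropped for it, so the LP stays solvable.
    _, sol = optimize_edge_weights(two_node_lp)
    assert sol.relaxed_sources == ["A"]


def test_flows_above_one_are_clipped_in_returned_network():
    # B's incoming equality forces X = e_B / e_A = 4 > 1
    net = Dmin("d")
    net.add_node("A", expression=1.0)
    net.add_node("B", expression=4.0)
    net.add_edge("A", "B", 1.0)
    weighted, sol = optimize_edge_weights(net)
    assert sol.flows[("A", "B")] == pytest.approx(4.0, abs=1e-6)
    assert weighted.weight("A", "B") == 1.0
    assert sol.clipped_edges == [("A", "B")]


@given(st.floats(min_value=0.1, max_value=50.0))
def test_scale_invariance(c):
    """Scaling all expression scores by c > 0 leaves flows unchanged and
    scales slacks and objective by c (both constraint families are
    homogeneous in e).  The chain topology pins a unique optimal flow, so
    the X vector itself is comparable across scales."""
    base = Dmin("d")
    for node, e in [("A", 2.0), ("B", 1.0), ("C", 3.0)]:
        base.add_node(node, expression=e)
    base.add_edge("A", "B", 1.0)
    base.add_edge("B", "C", 1.0)
    scaled = Dmin("d")
    for node in base.nodes():
        scaled.add_node(node, expression=c * base.expression(node))
    for u, v, w in base.edges():
        scaled.add_edge(u, v, w)
    _, sol1 = optimize_edge_weights(base)
    _, sol2 = optimize_edge_weights(scaled)
    for edge in sol1.flows:
        assert sol2.flows[edge] == pytest.approx(sol1.flows[edge], abs=1e-6)
    assert sol2.objective == pytest.approx(c * sol1.objective, rel=1e-6, abs=1e-6)


def test_optimality_beats_random_feasible_points():
    """Two parents feeding one child leave a one-parameter family of flows
    satisfying the incoming equality; the LP optimum is <= the objective of
    1,000 grid/random samples from that family."""
    net = Dmin("d")
    net.add_node("A", expression=2.0)
    net.add_node("B", expression=1.0)
    net.add_node("C", expression=1.5)
    net.add_edge("A", "C", 1.0)
    net.add_edge("B", "C", 1.0)
    _, sol = optimize_edge_weights(net)
    e = {"A": 2.0, "B": 1.0, "C": 1.5}
    rng = np.random.default_rng(0)
    # incoming at C: 2*X_AC + 1*X_BC = 1.5 with both flows >= 0
    ts = np.concatenate([np.linspace(0.0, 0.75, 500), rng.uniform(0, 0.75, 500)])
    for x_ac in ts:
        x_bc = 1.5 - 2.0 * x_ac
        slacks = [
            e["A"] - e["A"] * x_ac,
            e["B"] - e["B"] * x_bc,
            e["C"],  # sink: no out-edges
        ]
        objective = sum(abs(s) for s in slacks)
        assert sol.objective <= objective + 1e-6


def test_zero_expression_node_allowed():
    net = Dmin("d")
    net.add_node("A", expression=2.0)
    net.add_node("B", expression=2.0)
    net.add_node("Z", expression=0.0)
    net.add_edge("A", "B", 1.0)
    net.add_edge("Z", "B", 1.0)  # contributes nothing: e_Z * X = 0
    _, sol = optimize_edge_weights(net)
    assert sol.slacks["Z"] == pytest.approx(0.0, abs=1e-6)
    assert sol.objective == pytest.approx(2.0, abs=1e-6)


def test_deterministic_resolution(two_node_lp):
    _, sol1 = optimize_edge_weights(two_node_lp)
    _, sol2 = optimize_edge_weights(two_node_lp)
    assert sol1.flows == sol2.flows and sol1.slacks == sol2.slacks


# -- constant rescoring ------------------------------------------------------

def test_rescore_constant_sets_every_weight():
    cfg = FixtureConfig(n_nodes=6, edge_density=0.5, rng_seed=1)
    net = generate_random_dmin(cfg)
    out = rescore_constant(net, 0.01)
    assert out.n_edges == net.n_edges
    assert all(w == 0.01 for _, _, w in out.edges())


@pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
def test_rescore_constant_rejects_out_of_range(bad):
    net = Dmin("d")
    net.add_edge("a", "b", 0.5)
    with pytest.raises(ValidationError):
        rescore_constant(net, bad)


def test_rescore_idempotent_and_commutes_with_filter():
    cfg = FixtureConfig(
        n_nodes=8, edge_density=0.4, weight_distribution=("uniform01",), rng_seed=2
    )
    net = generate_random_dmin(cfg)
    once = rescore_constant(net, 0.01)
    twice = rescore_constant(once, 0.01)
    assert once.edges() == twice.edges()
    # filter-then-rescore equals rescore applied after the same filter on
    # confidence metadata (filtering keys on stored confidence, not weight)
    a = rescore_constant(filter_high_confidence(net, 0.5), 0.01)
    b = filter_high_confidence(net, 0.5)
    b = rescore_constant(b, 0.01)
    assert a.edges() == b.edges()


# -- verification report -----------------------------------------------------

def test_verify_passes_solver_output(two_node_lp, chain_lp):
    for net in (two_node_lp, chain_lp):
        weighted, sol = optimize_edge_weights(net)
        report = verify_lp_solution(weighted, sol, tol=1e-6)
        assert report["passed"], report


def test_verify_detects_hand_perturbation(two_node_lp):
    weighted, sol = optimize_edge_weights(two_node_lp)
    sol.flows[("A", "B")] = 0.9  # incoming at B becomes 2*0.9 = 1.8 vs e_B = 2
    report = verify_lp_solution(weighted, sol, tol=1e-6)
    assert not report["passed"]
    assert report["max_incoming_residual"] == pytest.approx(0.2, abs=1e-9)


def test_verify_flags_empty_flows(two_node_lp):
    weighted, _ = optimize_edge_weights(two_node_lp)
    empty = LpSolution(flows={}, slacks={}, objective=0.0, status="optimal")
    report = verify_lp_solution(weighted, empty, tol=1e-6)
    assert not report["passed"]
    assert report["max_incoming_residual"] > 0
    assert report["max_outgoing_residual"] > 0


def test_verify_on_random_networks():
    """Solver output verifies at 1e-6 on a batch of random annotated graphs."""
    checked = 0
    for seed in range(40):
        cfg = FixtureConfig(
            n_nodes=6,
            edge_density=0.45,
            expression_distribution=("lognormal", 0.0, 0.7),
            rng_seed=seed,
        )
        net = generate_random_dmin(cfg)
        if net.n_edges == 0:
            continue
        weighted, sol = optimize_edge_weights(net)
        report = verify_lp_solution(weighted, sol, tol=1e-6)
        assert report["passed"], (seed, report)
        checked += 1
    assert checked >= 30
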