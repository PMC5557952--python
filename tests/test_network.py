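"""Expression tables, network construction, filtering and I/O."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mircascade import (
    Dmin,
    ExpressionRecord,
    ExpressionTable,
    FormatError,
    NotFoundError,
    ValidationError,
    aggregate_expression,
    attach_expression,
    toy_cascade_fixture,
    filter_high_confidence,
    read_expression_table,
    read_network,
    write_network,
)


# -- expression CSV ----------------------------------------------------------

def test_read_expression_table_parses_rows(tmp_path):
    p = tmp_path / "expr.csv"
    p.write_text("mirna,disease,fold_change\nm1,d1,2.0\nm2,d1,8.0\nm3,d1,4.0\n")
    table = read_expression_table(p)
    assert len(table) == 3
    assert [r.fold_change for r in table] == [2.0, 8.0, 4.0]
    assert table.records[0].mirna_id == "m1"


def test_read_expression_table_rejects_nonpositive_with_row_number(tmp_path):
    p = tmp_path / "expr.csv"
    p.write_text("mirna,disease,fold_change\nm1,d1,2.0\nm2,d1,0\n")
    with pytest.raises(ValidationError, match="row 3"):
        read_expression_table(p)


def test_read_expression_table_missing_column_named(tmp_path):
    p = tmp_path / "expr.csv"
    p.write_text("mirna,disease\nm1,d1\n")
    with pytest.raises(FormatError, match="fold_change"):
        read_expression_table(p)


def test_read_expression_table_header_only_is_empty(tmp_path):
    p = tmp_path / "expr.csv"
    p.write_text("mirna,disease,fold_change\n")
    assert len(read_expression_table(p)) == 0


# -- aggregation -------------------------------------------------------------

@pytest.mark.parametrize(
    "fold_changes,expected",
    [
        ([2.0, 8.0], 2.0),  # mean of log2 {1, 3}
        ([4.0], 2.0),
        ([0.25, 4.0], 2.0),  # |−2| and |2| under the magnitude policy
    ],
)
def test_aggregate_expression_examples(fold_changes, expected):
    table = ExpressionTable(
        [ExpressionRecord("m", "d", fc) for fc in fold_changes]
    )
    assert aggregate_expression(table, "m", "d") == pytest.approx(expected)


def test_aggregate_expression_missing_pair():
    with pytest.raises(NotFoundError):
        aggregate_expression(ExpressionTable(), "m", "d")


@given(st.floats(min_value=0.01, max_value=100.0), st.integers(1, 5))
def test_aggregate_of_identical_fold_changes_is_abs_log2(fc, k):
    table = ExpressionTable([ExpressionRecord("m", "d", fc)] * k)
    assert aggregate_expression(table, "m", "d") == pytest.approx(
        abs(math.log2(fc))
    )


def test_record_rejects_nonpositive_fold_change():
    with pytest.raises(ValidationError):
        ExpressionRecord("m", "d", 0.0)


# -- high-confidence filtering ----------------------------------------------

def _three_edge_net():
    net = Dmin("d")
    net.add_edge("a", "b", 0.95)
    net.add_edge("b", "c", 0.90)
    net.add_edge("c", "a", 0.89)
    return net


def test_filter_boundary_inclusive():
    hc = filter_high_confidence(_three_edge_net(), 0.9)
    kept = {(u, v) for u, v, _ in hc.edges()}
    assert kept == {("a", "b"), ("b", "c")}
    # original probabilities retained as metadata, weight sentinel applied
    assert hc.graph["a"]["b"]["confidence"] == 0.95
    assert hc.graph.graph["weights_discarded"]


def test_filter_threshold_zero_keeps_all():
    assert filter_high_confidence(_three_edge_net(), 0.0).n_edges == 3


def test_filter_all_below_threshold_gives_empty_network():
    hc = filter_high_confidence(_three_edge_net(), 0.99)
    assert hc.n == 0 and hc.n_edges == 0


def test_filter_rejects_out_of_range_threshold():
    with pytest.raises(ValidationError):
        filter_high_confidence(_three_edge_net(), 1.5)


@given(st.floats(min_value=0.0, max_value=1.0))
def test_filter_idempotent(threshold):
    once = filter_high_confidence(_three_edge_net(), threshold)
    twice = filter_high_confidence(once, threshold)
    assert once.edges() == twice.edges()


@given(
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
def test_filter_monotone_in_threshold(t1, t2):
    lo, hi = min(t1, t2), max(t1, t2)
    at_hi = {(u, v) for u, v, _ in filter_high_confidence(_three_edge_net(), hi).edges()}
    at_lo = {(u, v) for u, v, _ in filter_high_confidence(_three_edge_net(), lo).edges()}
    assert at_hi <= at_lo


# -- expression attachment ---------------------------------------------------

def test_attach_expression_annotates_all_nodes(small_table):
    net = Dmin("d1")
    net.add_edge("m1", "m2", 1.0)
    net.add_edge("m2", "m3", 1.0)
    hce = attach_expression(net, small_table)
    assert hce.expression("m1") == pytest.approx(2.0)  # mean |log2| of {2, 8}
    assert hce.expression("m2") == pytest.approx(2.0)
    assert hce.expression("m3") == pytest.approx(2.0)  # |log2 0.25|


def test_attach_expression_removes_unscored_nodes(small_table, caplog):
    net = Dmin("d1")
    net.add_edge("m1", "m2", 1.0)
    net.add_edge("m2", "m9", 1.0)  # m9 has no record for d1
    with caplog.at_level("WARNING"):
        hce = attach_expression(net, small_table)
    assert "m9" not in hce
    assert set(hce.nodes()) == {"m1", "m2"}
    assert any("m9" in rec.message for rec in caplog.records)


def test_attach_expression_uses_disease_specific_records(small_table):
    net = Dmin("d2")
    net.add_edge("m1", "m2", 1.0)
    hce = attach_expression(net, small_table)
    # m2 has no d2 record, so only m1 survives, with its d2 score |log2 16|
    assert set(hce.nodes()) == {"m1"}
    assert hce.expression("m1") == pytest.approx(4.0)


def test_attach_refuses_already_annotated_network(small_table):
    net = Dmin("d1")
    net.add_node("m1", expression=1.0)
    net.add_edge("m1", "m2", 1.0)
    with pytest.raises(ValidationError):
        attach_expression(net, small_table)


# -- structural invariants ---------------------------------------------------

def test_self_loop_rejected():
    net = Dmin("d")
    with pytest.raises(ValidationError):
        net.add_edge("a", "a", 0.5)


def test_weight_out_of_range_rejected():
    net = Dmin("d")
    with pytest.raises(ValidationError):
        net.add_edge("a", "b", 1.2)


def test_duplicate_edge_keeps_max_weight():
    net = Dmin("d")
    net.add_edge("a", "b", 0.3)
    net.add_edge("a", "b", 0.8)
    net.add_edge("a", "b", 0.5)
    assert net.weight("a", "b") == 0.8


# -- round-trip I/O ----------------------------------------------------------

def test_round_trip_toy_network(tmp_path, toy_net):
    p = tmp_path / "net.csv"
    write_network(toy_net, p)
    back = read_network(p, disease_id=toy_net.disease_id)
    assert back == toy_net


def test_round_trip_with_expression(tmp_path):
    net = Dmin("dz")
    net.add_node("m1", expression=1.2345678901234)
    net.add_node("m2", expression=0.5)
    net.add_edge("m1", "m2", 0.987654321)
    p = tmp_path / "net.csv"
    write_network(net, p)
    back = read_network(p, disease_id="dz")
    assert back == net


def test_read_network_rejects_weight_above_one(tmp_path):
    p = tmp_path / "net.csv"
    p.write_text("source,target,weight\na,b,1.2\n")
    with pytest.raises(ValidationError, match="line 2"):
        read_network(p)


def test_read_network_rejects_bad_header(tmp_path):
    p = tmp_path / "net.csv"
    p.write_text("src,dst,w\na,b,0.5\n")
    with pytest.raises(FormatError):
        read_network(p)


def test_edgeless_network_round_trip(tmp_path):
    net = Dmin("empty")
    p = tmp_path / "net.csv"
    write_network(net, p)
    back = read_network(p, disease_id="empty")
    assert back.n == 0 and back.n_edges == 0
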