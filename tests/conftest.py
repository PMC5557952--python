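import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mircascade import Dmin, ExpressionRecord, ExpressionTable, toy_cascade_fixture


@pytest.fixture
def toy_net():
    return toy_cascade_fixture()


@pytest.fixture
def two_node_lp():
    """A->B with e_A = e_B = 2; optimum: X=1, s=(0, 2), objective 2."""
    net = Dmin("two")
    net.add_node("A", expression=2.0)
    net.add_node("B", expression=2.0)
    net.add_edge("A", "B", 1.0)
    return net


@pytest.fixture
def chain_lp():
    """A->B->C with all e = 1; optimum: X=(1,1), s=(0,0,1), objective 1."""
    net = Dmin("chain")
    for node in "ABC":
        net.add_node(node, expression=1.0)
    net.add_edge("A", "B", 1.0)
    net.add_edge("B", "C", 1.0)
    return net


@pytest.fixture
def small_table():
    return ExpressionTable(
        [
            ExpressionRecord("m1", "d1", 2.0, "up", "s1"),
            ExpressionRecord("m1", "d1", 8.0, "up", "s2"),
            ExpressionRecord("m2", "d1", 4.0, "down"),
            ExpressionRecord("m3", "d1", 0.25, "down"),
            ExpressionRecord("m1", "d2", 16.0, "up"),
        ]
    )
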