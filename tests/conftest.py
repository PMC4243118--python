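import itertools

import pytest

from litppi import ComplexSet, PPINetwork


@pytest.fixture
def star4() -> PPINetwork:
    """Unweighted star: hub H plus three leaves (4 proteins, 3 edges)."""
    return PPINetwork.from_edges([("H", "L1"), ("H", "L2"), ("H", "L3")])


@pytest.fixture
def star4_closed(star4) -> PPINetwork:
    """The star with one extra leaf-leaf edge (4 proteins, 4 edges)."""
    g = star4.graph.copy()
    g.add_edge("L1", "L2")
    return PPINetwork(g)


def clique(names) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(names), 2))


@pytest.fixture
def two_cliques() -> PPINetwork:
    """Two disjoint 5-cliques plus two isolated edges."""
    edges = clique("ABCDE") + clique("VWXYZ") + [("m1", "m2"), ("n1", "n2")]
    return PPINetwork.from_edges(edges)


@pytest.fixture
def ref_pair() -> ComplexSet:
    return ComplexSet.from_sets([{"A", "B", "C"}, {"D", "E", "F"}], prefix="ref")


@pytest.fixture
def pred_pair() -> ComplexSet:
    return ComplexSet.from_sets([{"A", "B", "D"}, {"D", "E", "F"}], prefix="pred")
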