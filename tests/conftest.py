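import networkx as nx
import pytest

from lbcc import ComplexCollection, EssentialAnnotation, PPINetwork


def net_from(edges, extra_nodes=()):
    return PPINetwork.from_edges(edges, extra_nodes=extra_nodes)


@pytest.fixture
def triangle():
    return net_from([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star4():
    """K1,4: hub h with four leaves."""
    return net_from([("h", f"l{i}") for i in range(4)])


@pytest.fixture
def path5():
    """Path a-b-c-d-e."""
    return net_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def k4():
    g = nx.complete_graph(4)
    g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
    return PPINetwork(g)


@pytest.fixture
def toy_dataset(tmp_path):
    """Small on-disk dataset: edge list, essential list, complex catalog."""
    edges = tmp_path / "edges.tsv"
    edges.write_text("a\tb\nb\tc\na\tc\nc\td\nd\te\n")
    ess = tmp_path / "ess.txt"
    ess.write_text("a\nc\n")
    cplx = tmp_path / "cplx.tsv"
    cplx.write_text("c1\ta\tb\tc\nc2\tc\td\n")
    return edges, ess, cplx


@pytest.fixture
def annotation():
    return EssentialAnnotation(frozenset({"a", "c"}))


@pytest.fixture
def two_complexes():
    return ComplexCollection((("c1", frozenset({"a", "b", "c"})),
                              ("c2", frozenset({"c", "d"}))))
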