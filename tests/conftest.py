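import networkx as nx
import pytest

from netscreen import FixtureSpec, Interactome, NodeSet, generate_graph


@pytest.fixture
def p5():
    """Path v0 - v1 - v2 - v3 - v4."""
    g = nx.Graph()
    nx.add_path(g, [f"v{i}" for i in range(5)])
    return Interactome(g, name="p5")


@pytest.fixture
def star4():
    """Star with center c and leaves l1..l4."""
    g = nx.Graph()
    g.add_edges_from([("c", f"l{i}") for i in range(1, 5)])
    return Interactome(g, name="star4")


@pytest.fixture
def k4():
    return Interactome(nx.complete_graph(["a", "b", "c", "d"]), name="k4")


@pytest.fixture
def single_edge():
    return Interactome(nx.Graph([("a", "b")]), name="edge")


@pytest.fixture
def weighted_triangle():
    """Triangle with weights 1, 1, 3: the heavy edge's endpoints are closer
    via the detour."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    g.add_edge("a", "c", weight=3.0)
    return Interactome(g, name="wtri")


@pytest.fixture
def er_factory():
    def make(n=30, p=0.1, seed=0, weighted=False):
        return generate_graph(FixtureSpec(kind="erdos_renyi", n=n, p=p, seed=seed, weighted=weighted))

    return make


def nodeset(*members, name="S"):
    return NodeSet(name=name, members=frozenset(members))
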