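import networkx as nx
import pytest


def as_str(graph: nx.Graph) -> nx.Graph:
    """Relabel integer nodes to zero-padded strings (stable sort order)."""
    return nx.relabel_nodes(graph, lambda i: f"n{i:02d}")


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = as_str(nx.gnp_random_graph(n, p, seed=seed))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


@pytest.fixture
def k4() -> nx.Graph:
    return as_str(nx.complete_graph(4))


@pytest.fixture
def two_k3() -> nx.Graph:
    """Two disjoint triangles {a0,a1,a2} and {b0,b1,b2}."""
    g = nx.Graph()
    g.add_edges_from([("a0", "a1"), ("a0", "a2"), ("a1", "a2")])
    g.add_edges_from([("b0", "b1"), ("b0", "b2"), ("b1", "b2")])
    return g


@pytest.fixture
def bridged_k3(two_k3) -> nx.Graph:
    """Two triangles joined by the bridge edge a0-b0 (m = 7)."""
    g = two_k3.copy()
    g.add_edge("a0", "b0")
    return g
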