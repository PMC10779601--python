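import networkx as nx
import numpy as np
import pytest

from endoprox import GeneSet, InteractomeGraph, ModuleCatalog


def make_graph(edges, nodes=(), name="test"):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return InteractomeGraph(graph=g, name=name)


@pytest.fixture
def path5():
    """Path graph 1-2-3-4-5."""
    return make_graph([("1", "2"), ("2", "3"), ("3", "4"), ("4", "5")])


@pytest.fixture
def k6():
    """Complete graph on 6 nodes a..f."""
    nodes = list("abcdef")
    return make_graph(
        [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
    )


@pytest.fixture
def small_catalog():
    return ModuleCatalog(
        modules=[
            GeneSet("m1", frozenset({"a", "b"}), category="amyloidosis"),
            GeneSet("m2", frozenset({"b", "c"}), category="tauopathy"),
        ],
        source="fixture",
    )


def random_connected_graph(rng, max_nodes=50, min_nodes=5):
    """Random connected graph (LCC of a G(n,p)) with min_nodes..max_nodes nodes."""
    while True:
        n = int(rng.integers(min_nodes, max_nodes + 1))
        p = float(rng.uniform(0.08, 0.4))
        seed = int(rng.integers(0, 2**31))
        g = nx.gnp_random_graph(n, p, seed=seed)
        comp = max(nx.connected_components(g), key=len)
        if len(comp) < min_nodes:
            continue
        sub = nx.relabel_nodes(g.subgraph(comp).copy(), {i: f"n{i}" for i in comp})
        return InteractomeGraph(graph=sub, name="rand")


def floyd_warshall_hops(g: InteractomeGraph):
    """Brute-force all-pairs hop distances (independent oracle)."""
    nodes = sorted(g.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in g.graph.edges:
        d[idx[u], idx[v]] = 1.0
        d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return nodes, idx, d


def brute_closest_distance(g: InteractomeGraph, A, B):
    """Double-loop closest distance over Floyd-Warshall hops (oracle)."""
    _, idx, d = floyd_warshall_hops(g)
    a_idx = [idx[a] for a in A]
    b_idx = [idx[b] for b in B]
    total = sum(min(d[i, j] for j in b_idx) for i in a_idx)
    total += sum(min(d[i, j] for i in a_idx) for j in b_idx)
    return total / (len(a_idx) + len(b_idx))
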