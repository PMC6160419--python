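import itertools
import math

import networkx as nx
import pytest

from netmod import GeneSet
from netmod.cab import edge_length


def wgraph(edges):
    """Build a weighted graph from (u, v, w) triples."""
    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, weight=w)
    return G


@pytest.fixture
def path_ab():
    """Two-node path with unit confidence."""
    return wgraph([("A", "B", 1.0)])


@pytest.fixture
def triangle_weighted():
    """Triangle where the direct A-B edge is weak and the detour is strong."""
    return wgraph([("A", "B", 0.1), ("A", "C", 0.9), ("C", "B", 0.9)])


@pytest.fixture
def star5():
    """Star: hub H with 4 unit-confidence leaves."""
    return wgraph([("H", f"L{i}", 1.0) for i in range(1, 5)])


def geneset(*genes, name="set"):
    return GeneSet.from_iterable(name, genes)


def exact_steiner_cost(G, terminals, p):
    """Minimum Steiner tree cost by exhaustive search: over every node subset
    containing the terminals, the MST cost of the induced subgraph (the
    optimal tree spans some such subset, and the MST over that subset costs
    no more)."""
    optional = [n for n in sorted(G.nodes) if n not in terminals]
    best = math.inf
    for r in range(len(optional) + 1):
        for extra in itertools.combinations(optional, r):
            subset = set(terminals) | set(extra)
            sub = nx.Graph()
            sub.add_nodes_from(subset)
            for u, v, d in G.subgraph(subset).edges(data=True):
                sub.add_edge(u, v, cost=edge_length(d["weight"], p))
            if sub.number_of_nodes() and nx.is_connected(sub):
                mst = nx.minimum_spanning_tree(sub, weight="cost")
                cost = sum(mst[u][v]["cost"] for u, v in mst.edges)
                best = min(best, cost)
    return best


def random_weighted_graph(rng, n, p_edge=0.4, connected=True):
    """Random graph with confidences in (0.05, 1]; optionally retried until
    connected."""
    while True:
        G = nx.Graph()
        G.add_nodes_from(f"N{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    G.add_edge(f"N{i}", f"N{j}", weight=0.05 + 0.95 * rng.random())
        if not connected or (n > 0 and nx.is_connected(G)):
            return G
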