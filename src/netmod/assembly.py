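"""Assembly of the disease module: connect neighborhood components and
significant candidates into one subnetwork via a greedy Steiner heuristic.

The terminal set (neighborhood genes plus significantly close candidates)
usually induces several disconnected pieces.  The heuristic repeatedly joins
the two pieces with the cheapest connecting path under the same ln(p/w) edge
costs used for closeness scoring, then prunes the resulting tree of
non-terminal leaves.  The non-terminal genes that remain are the module's
"linker" genes.  Path-merging heuristics of this family are classical
2-approximations of the minimum Steiner tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .cab import _weight_fn
from .interactome import GeneSet
from .neighborhood import NetworkNeighborhood

logger = logging.getLogger("netmod")

__all__ = ["DiseaseModule", "greedy_steiner", "assemble_module"]


@dataclass
class DiseaseModule:
    terminals: GeneSet
    linkers: GeneSet
    members: GeneSet
    edges: list[tuple[str, str, float]]  # induced subgraph edge list with confidences
    total_size: int
    tree_edges: list[tuple[str, str]] = field(default_factory=list)
    tree_cost: float = 0.0
    provenance: dict[str, str] = field(default_factory=dict)


def _components(G: nx.Graph, members: set[str]) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(G.subgraph(members))]


def _cheapest_bridge(G: nx.Graph, comps: list[set[str]], wfn):
    """Cheapest path between any two of the current components.

    Returns (cost, path) with deterministic tie-breaks: smallest cost, then
    lexicographically smallest path node sequence.
    """
    best: tuple[float, tuple[str, ...]] | None = None
    membership: dict[str, int] = {}
    for i, c in enumerate(comps):
        for g in c:
            membership[g] = i
    for i, comp in enumerate(comps):
        dist, paths = nx.multi_source_dijkstra(G, sorted(comp), weight=wfn)
        for target in sorted(dist):
            j = membership.get(target)
            if j is None or j == i:
                continue
            path = tuple(paths[target])
            if path[0] > path[-1]:
                path = path[::-1]
            cand = (dist[target], path)
            if best is None or cand < best:
                best = cand
    return best


def greedy_steiner(G: nx.Graph, terminals: GeneSet, p: float = math.e) -> DiseaseModule:
    """Connect the terminal genes by iterative component merging.

    Starting from the connected components induced by the terminals, the two
    components with the smallest inter-component shortest path (under
    ln(p/w) costs) are joined by adding the path's interior nodes; this
    repeats until one component remains.  A minimum spanning tree of the
    resulting node set is then pruned of non-terminal leaves, so every
    surviving linker lies on a tree path between two terminals.

    Terminals split across different connected components of the interactome
    itself are assembled per component, with a warning.
    """
    mapped = terminals.mapped(G)
    unmapped = terminals.members - mapped
    if unmapped:
        raise ValueError(f"unmapped terminal(s): {sorted(unmapped)}")
    if not mapped:
        raise ValueError("no terminals given")
    wfn = _weight_fn(p)

    # group terminals by interactome component; join only within groups
    groups: list[set[str]] = []
    for comp in nx.connected_components(G):
        hit = comp & mapped
        if hit:
            groups.append(set(hit))
    if len(groups) > 1:
        logger.warning(
            "terminals span %d interactome components; assembling each separately", len(groups)
        )

    members: set[str] = set()
    tree_edges: list[tuple[str, str]] = []
    tree_cost = 0.0
    for group in groups:
        nodes = set(group)
        comps = _components(G, nodes)
        while len(comps) > 1:
            bridge = _cheapest_bridge(G, comps, wfn)
            assert bridge is not None, "components of one interactome component must be joinable"
            _, path = bridge
            nodes.update(path)
            comps = _components(G, nodes)
        # spanning tree of the merged node set, then prune non-terminal leaves
        sub = nx.Graph()
        for u, v, data in G.subgraph(nodes).edges(data=True):
            sub.add_edge(u, v, cost=wfn(u, v, data))
        if len(nodes) == 1:
            tree = nx.Graph()
            tree.add_nodes_from(nodes)
        else:
            tree = nx.minimum_spanning_tree(sub, weight="cost")
        pruned = True
        while pruned:
            pruned = False
            for leaf in [n for n in tree.nodes if tree.degree(n) <= 1 and n not in mapped]:
                tree.remove_node(leaf)
                pruned = True
        members.update(tree.nodes)
        tree_edges.extend(tuple(sorted(e)) for e in tree.edges)
        tree_cost += sum(tree[u][v]["cost"] for u, v in tree.edges)

    linkers = members - mapped
    induced = G.subgraph(members)
    edges = sorted(
        (min(u, v), max(u, v), float(d.get("weight", 1.0))) for u, v, d in induced.edges(data=True)
    )
    return DiseaseModule(
        terminals=GeneSet(name="terminals", members=frozenset(mapped)),
        linkers=GeneSet(name="linkers", members=frozenset(linkers)),
        members=GeneSet(name="module", members=frozenset(members)),
        edges=edges,
        total_size=len(members),
        tree_edges=sorted(tree_edges),
        tree_cost=tree_cost,
    )


def assemble_module(
    neighborhood: NetworkNeighborhood,
    significant: GeneSet,
    G: nx.Graph,
    p: float = math.e,
) -> DiseaseModule:
    """Disease module = neighborhood genes + significant candidates, joined
    into one subnetwork; each member labeled seed / neighborhood / candidate
    / linker in the provenance table."""
    terminal_genes = neighborhood.neighborhood.members | significant.mapped(G)
    module = greedy_steiner(
        G, GeneSet(name="terminals", members=frozenset(terminal_genes)), p=p
    )
    seeds = neighborhood.seeds_mapped.members
    prov = {}
    for g in sorted(module.members.members):
        if g in seeds:
            prov[g] = "seed"
        elif g in neighborhood.neighborhood:
            prov[g] = "neighborhood"
        elif g in significant:
            prov[g] = "candidate"
        else:
            prov[g] = "linker"
    module.provenance = prov
    return module
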