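"""Reading, validating and summarizing confidence-weighted interactomes.

The interactome is an undirected :class:`networkx.Graph` whose nodes are
uppercased gene symbols and whose edges carry a ``weight`` attribute: the
interaction confidence score w in [0, 1].  All downstream stages (random-walk
ranking, weighted closeness, Steiner assembly) operate on this graph type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("netmod")

__all__ = [
    "GeneSet",
    "NetworkSummary",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "write_gene_set",
    "network_summary",
]


class EdgeListError(ValueError):
    """Raised for malformed or invalid edge-list input."""


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. seeds, a module, a signature)."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(_norm(g) for g in genes if _norm(g)))

    @property
    def size(self) -> int:
        return len(self.members)

    def mapped(self, G: nx.Graph) -> frozenset[str]:
        """Members present in the graph."""
        return self.members & set(G.nodes)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class NetworkSummary:
    """Global topology statistics of an interactome."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    clustering_coefficient: float
    degree_tail: dict[int, tuple[int, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "clustering_coefficient": self.clustering_coefficient,
            "degree_tail": {
                str(t): {"count": c, "fraction": f}
                for t, (c, f) in self.degree_tail.items()
            },
        }
        return json.dumps(payload, indent=2)


def read_edge_list(path: str | Path, header: bool = False) -> nx.Graph:
    """Read a tab-separated ``geneA geneB [confidence]`` edge list.

    Symbols are uppercased and whitespace-stripped; self-loops are dropped
    (with a logged count); duplicate edges are collapsed keeping the maximum
    confidence; a missing confidence column defaults to 1.0.  Edges with zero
    confidence are dropped: they correspond to infinite weighted distance and
    are equivalent to absent edges.
    """
    G = nx.Graph()
    n_self_loops = 0
    n_zero_conf = 0
    with open(path) as fh:
        lines = iter(enumerate(fh, start=1))
        if header:
            next(lines, None)
        for lineno, line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise EdgeListError(f"line {lineno}: expected at least 2 columns, got {len(parts)}")
            a, b = _norm(parts[0]), _norm(parts[1])
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListError(f"line {lineno}: bad confidence {parts[2]!r}") from exc
            else:
                w = 1.0
            if not (0.0 <= w <= 1.0):
                raise EdgeListError(f"line {lineno}: confidence {w} outside [0, 1]")
            if a == b:
                n_self_loops += 1
                continue
            if w == 0.0:
                n_zero_conf += 1
                continue
            if G.has_edge(a, b):
                G[a][b]["weight"] = max(G[a][b]["weight"], w)
            else:
                G.add_edge(a, b, weight=w)
    if n_self_loops:
        logger.info("dropped %d self-loop(s)", n_self_loops)
    if n_zero_conf:
        logger.info("dropped %d zero-confidence edge(s)", n_zero_conf)
    return G


def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Write the graph as a sorted TSV edge list (round-trips with the reader)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{a}\t{b}\t{G[a][b].get('weight', 1.0):.10g}\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene list; ``#`` comments and blanks ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                genes.append(line)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def network_summary(G: nx.Graph, degree_thresholds: Iterable[int] = ()) -> NetworkSummary:
    """Summarize the interactome: N, M, mean degree 2M/N, average local
    clustering (degree-<2 nodes contribute 0), and the fraction of nodes at or
    above each degree threshold.
    """
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n == 0:
        raise ValueError("cannot summarize an empty graph")
    degrees = dict(G.degree())
    tail: dict[int, tuple[int, float]] = {}
    for t in degree_thresholds:
        count = sum(1 for d in degrees.values() if d >= t)
        tail[int(t)] = (count, count / n)
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        mean_degree=2.0 * m / n,
        clustering_coefficient=nx.average_clustering(G),
        degree_tail=tail,
    )
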