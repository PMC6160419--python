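"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates each input class the method consumes:

* a scale-free, confidence-weighted interactome (preferential attachment
  backbone; Beta-distributed confidences kept away from 0);
* a planted disease module: a node subset densified with high-confidence
  edges, a few of whose members are designated seed genes;
* gene-level association p-values enriched (Beta(a, 1), a < 1) on module
  genes and uniform elsewhere;
* a pull-down candidate list in which a small fraction of partners is wired
  adjacent to the module and the rest are drawn from distant nodes;
* limma-style differential-expression tables with inflated |logFC| on
  module genes and Benjamini-Hochberg adjusted p-values.

Every generator is deterministic given the configuration's ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import GeneSet
from .validation import DETable

__all__ = [
    "SimConfig",
    "generate_interactome",
    "plant_module",
    "generate_gene_pvalues",
    "generate_pulldown",
    "generate_de_table",
    "write_fixture_dir",
]

_MIN_CONF = 0.05  # confidences rescaled into (0.05, 1]: zero-confidence edges are meaningless


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline."""

    n_nodes: int = 400
    attachment_edges: int = 3
    weight_dist: tuple[float, float] = (2.0, 2.0)  # Beta(alpha, beta) on (0, 1]
    module_size: int = 30
    module_density: float = 0.3
    n_seeds: int = 8
    pval_enrichment: float = 0.2  # Beta(a, 1) shape for module gene p-values
    n_partners: int = 96
    frac_proximal: float = 9 / 96
    fc_effect: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be < n_nodes")
        if self.n_seeds > self.module_size:
            raise ValueError("n_seeds must be <= module_size")
        if not 0 <= self.frac_proximal <= 1:
            raise ValueError("frac_proximal must be in [0, 1]")
        if self.n_nodes < 20:
            raise ValueError("n_nodes must be >= 20")


def _gene(i: int) -> str:
    return f"G{i:05d}"


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng((int(cfg.rng_seed) * 1_000_003 + stage) % (2**31 - 1))


def generate_interactome(cfg: SimConfig) -> nx.Graph:
    """Preferential-attachment backbone with Beta-distributed confidences."""
    rng = _rng(cfg, 1)
    # seed growth from an m-clique so every new node attaches m edges:
    # |E| = C(m,2) + (n - m) * m; for m = 1 the start must still contain an
    # edge for preferential attachment to act on, so K2 is used (a tree
    # results either way)
    m = cfg.attachment_edges
    backbone = nx.barabasi_albert_graph(
        cfg.n_nodes,
        m,
        seed=int(rng.integers(2**31 - 1)),
        initial_graph=nx.complete_graph(max(m, 2)),
    )
    a, b = cfg.weight_dist
    G = nx.Graph()
    G.add_nodes_from(_gene(i) for i in range(cfg.n_nodes))
    for u, v in sorted(backbone.edges):
        w = _MIN_CONF + (1 - _MIN_CONF) * float(rng.beta(a, b))
        G.add_edge(_gene(u), _gene(v), weight=w)
    return G


def plant_module(G: nx.Graph, cfg: SimConfig) -> tuple[nx.Graph, GeneSet, GeneSet]:
    """Densify a random node subset into a high-confidence module and pick
    seed genes inside it.  Edges are added among module members until the
    induced density reaches ``module_density``, each with confidence in
    [0.8, 1]."""
    rng = _rng(cfg, 2)
    nodes = sorted(G.nodes)
    module_nodes = sorted(rng.choice(nodes, size=cfg.module_size, replace=False))
    G = G.copy()
    pairs = [
        (a, b)
        for i, a in enumerate(module_nodes)
        for b in module_nodes[i + 1 :]
        if not G.has_edge(a, b)
    ]
    n_possible = cfg.module_size * (cfg.module_size - 1) // 2
    target_edges = int(np.ceil(cfg.module_density * n_possible))
    existing = n_possible - len(pairs)
    n_to_add = max(0, target_edges - existing)
    order = rng.permutation(len(pairs))
    for k in order[:n_to_add]:
        a, b = pairs[k]
        G.add_edge(a, b, weight=0.8 + 0.2 * float(rng.random()))
    seeds = sorted(rng.choice(module_nodes, size=cfg.n_seeds, replace=False))
    return (
        G,
        GeneSet.from_iterable("planted_module", module_nodes),
        GeneSet.from_iterable("seeds", seeds),
    )


def generate_gene_pvalues(G: nx.Graph, module: GeneSet, cfg: SimConfig) -> dict[str, float]:
    """Association p-values: Beta(a, 1) on module genes (enriched toward 0
    when a < 1), Uniform(0, 1) elsewhere."""
    rng = _rng(cfg, 3)
    pvals = {}
    for g in sorted(G.nodes):
        if g in module:
            p = float(rng.beta(cfg.pval_enrichment, 1.0))
        else:
            p = float(rng.random())
        pvals[g] = min(max(p, 1e-300), 1.0)
    return pvals


def generate_pulldown(G: nx.Graph, module: GeneSet, cfg: SimConfig) -> tuple[nx.Graph, GeneSet, GeneSet]:
    """Candidate (pull-down partner) list: a proximal fraction wired to at
    least 3 module genes with high confidence, the rest sampled from nodes
    at hop distance >= 2 from the module.  Returns the (possibly rewired)
    graph, all partners, and the planted-proximal subset."""
    rng = _rng(cfg, 4)
    n_prox = round(cfg.frac_proximal * cfg.n_partners)
    module_nodes = sorted(module.mapped(G))
    non_module = [g for g in sorted(G.nodes) if g not in module]
    adjacent = {g for g in non_module if any(nb in module for nb in G[g])}
    distant = [g for g in non_module if g not in adjacent]
    if len(distant) < cfg.n_partners:
        raise ValueError("not enough non-module, non-adjacent nodes for partners")
    chosen = [str(g) for g in rng.choice(distant, size=cfg.n_partners, replace=False)]
    proximal, background = chosen[:n_prox], chosen[n_prox:]
    G = G.copy()
    for g in proximal:
        k = int(rng.integers(3, 6))
        targets = rng.choice(module_nodes, size=k, replace=False)
        for t in targets:
            G.add_edge(g, str(t), weight=0.8 + 0.2 * float(rng.random()))
    return (
        G,
        GeneSet.from_iterable("partners", chosen),
        GeneSet.from_iterable("proximal_partners", proximal),
    )


def generate_de_table(
    G: nx.Graph, module: GeneSet, cfg: SimConfig, dataset_label: str = "synthetic", stage: int = 5
) -> DETable:
    """Differential-expression table over all network genes: background
    logFC ~ N(0, 1); module logFC ~ N(+/- fc_effect, 1) with random sign;
    p from a two-sided z-test of the drawn value; BH-adjusted p."""
    rng = _rng(cfg, stage)
    genes = sorted(G.nodes)
    logfc = rng.normal(0.0, 1.0, size=len(genes))
    for i, g in enumerate(genes):
        if g in module:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            logfc[i] = rng.normal(sign * cfg.fc_effect, 1.0)
    p = 2.0 * stats.norm.sf(np.abs(logfc))
    p = np.clip(p, 1e-300, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    adj_p = np.clip(adj_p, 1e-300, 1.0)
    frame = pd.DataFrame({"gene": genes, "logFC": logfc, "p": p, "adj_p": adj_p})
    return DETable(dataset=dataset_label, frame=frame)


def write_fixture_dir(cfg: SimConfig, outdir: str | Path, n_de_tables: int = 2) -> dict:
    """Generate a full fixture set on disk: edges.tsv, seeds.txt, gwas.tsv,
    partners.txt, de_*.tsv and truth.json (planted memberships)."""
    from .interactome import write_edge_list, write_gene_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G = generate_interactome(cfg)
    G, module, seeds = plant_module(G, cfg)
    pvals = generate_gene_pvalues(G, module, cfg)
    G, partners, proximal = generate_pulldown(G, module, cfg)

    write_edge_list(G, outdir / "edges.tsv")
    write_gene_set(seeds.members, outdir / "seeds.txt")
    write_gene_set(partners.members, outdir / "partners.txt")
    with open(outdir / "gwas.tsv", "w") as fh:
        fh.write("gene\tp\n")
        for g, p in sorted(pvals.items()):
            fh.write(f"{g}\t{p:.6g}\n")
    for i in range(n_de_tables):
        table = generate_de_table(G, module, cfg, dataset_label=f"de_{i + 1}", stage=5 + i)
        frame = table.frame.rename(
            columns={"gene": "gene", "logFC": "logFC", "p": "P.Value", "adj_p": "adj.P.Val"}
        )
        frame.to_csv(outdir / f"de_{i + 1}.tsv", sep="\t", index=False)
    truth = {
        "config": asdict(cfg),
        "module": sorted(module.members),
        "seeds": sorted(seeds.members),
        "partners": sorted(partners.members),
        "proximal_partners": sorted(proximal.members),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
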