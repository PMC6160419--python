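"""Validation of a disease module against differential-expression tables.

Four checks, all operating on limma-style tables (gene, logFC, P.Value,
adj.P.Val):

* fold-change comparison — are differentially expressed (DE) module genes
  more strongly dysregulated (larger |logFC|) than DE non-module genes?
* enrichment — is the module over-represented among DE genes, relative to
  all genes tested (hypergeometric tail)?
* connectivity-corrected control — the module is connected by construction,
  so its genes are also compared with *connected* random subsets of the DE
  genes, grown neighbor by neighbor in the interactome.
* annotation overlap — hypergeometric overlap of the module with an external
  signature (e.g. inflammation-related genes), reported as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .interactome import GeneSet

logger = logging.getLogger("netmod")

__all__ = [
    "DETable",
    "ValidationResult",
    "EnrichmentResult",
    "read_de_table",
    "foldchange_comparison",
    "enrichment_test",
    "connected_random_subset",
    "module_vs_connected_random",
    "overlap_test",
]

_COLUMN_ALIASES = {
    "gene": {"gene", "gene.symbol", "gene_symbol", "symbol", "genesymbol"},
    "logFC": {"logfc", "log_fc", "log2fc", "log2foldchange"},
    "p": {"p.value", "pvalue", "p_value", "p", "pval"},
    "adj_p": {"adj.p.val", "adj_p_val", "adjpval", "padj", "fdr", "adj.p.value", "adj_p"},
}


@dataclass
class DETable:
    """One dataset's differential-expression results."""

    dataset: str
    frame: pd.DataFrame  # columns: gene, logFC, p, adj_p

    def de_genes(self, p_thresh: float = 0.05, adjusted: bool = False) -> GeneSet:
        col = "adj_p" if adjusted else "p"
        hits = self.frame.loc[self.frame[col] < p_thresh, "gene"]
        return GeneSet.from_iterable(f"{self.dataset}_de", hits)

    @property
    def genes(self) -> GeneSet:
        return GeneSet.from_iterable(self.dataset, self.frame["gene"])


@dataclass
class ValidationResult:
    dataset: str
    n_module_de: int
    n_background_de: int
    median_absfc_module: float
    median_absfc_background: float
    u_stat: float
    p_value: float
    module_higher: bool


@dataclass
class EnrichmentResult:
    overlap: int
    set_size: int
    de_size: int
    universe: int
    fold: float
    p_value: float
    set_percent: int | None = None
    background_percent: int | None = None


def read_de_table(path: str | Path, dataset: str | None = None) -> DETable:
    """Read a limma-style TSV.  Column names are matched case-insensitively
    against common aliases; duplicate genes are collapsed keeping the row
    with the smallest unadjusted p-value."""
    raw = pd.read_csv(path, sep="\t")
    colmap = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for col in raw.columns:
            if col.strip().lower() in aliases:
                colmap[col] = canon
                break
        else:
            raise ValueError(f"missing required column for {canon!r} in {path}")
    df = raw.rename(columns=colmap)[["gene", "logFC", "p", "adj_p"]].copy()
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    df = df.sort_values("p", kind="stable").drop_duplicates("gene", keep="first")
    df = df.reset_index(drop=True)
    for col in ("p", "adj_p"):
        bad = df[(df[col] <= 0) | (df[col] > 1)]
        if len(bad):
            raise ValueError(f"{col} outside (0, 1] for genes {bad['gene'].tolist()[:5]}")
    return DETable(dataset=dataset or Path(path).stem, frame=df)


def _ranksum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney; exact enumeration for small samples, normal
    approximation above n = 20."""
    method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
    if method == "exact" and (len(set(x) | set(y)) < len(x) + len(y)):
        method = "asymptotic"  # exact null assumes no ties
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(p)


def foldchange_comparison(
    module: GeneSet, table: DETable, p_thresh: float = 0.05
) -> ValidationResult:
    """Compare |logFC| of DE module genes against DE non-module genes
    (two-sided rank-sum), filtering both at unadjusted p below the
    threshold."""
    df = table.frame
    de = df[df["p"] < p_thresh]
    in_module = de["gene"].isin(module.members)
    mod_fc = de.loc[in_module, "logFC"].abs().to_numpy()
    bg_fc = de.loc[~in_module, "logFC"].abs().to_numpy()
    if len(mod_fc) < 3 or len(bg_fc) < 3:
        raise ValueError(
            f"too few DE genes in {table.dataset}: module {len(mod_fc)}, background {len(bg_fc)}"
        )
    u, p = _ranksum(mod_fc, bg_fc)
    med_m, med_b = float(np.median(mod_fc)), float(np.median(bg_fc))
    return ValidationResult(
        dataset=table.dataset,
        n_module_de=len(mod_fc),
        n_background_de=len(bg_fc),
        median_absfc_module=med_m,
        median_absfc_background=med_b,
        u_stat=u,
        p_value=p,
        module_higher=med_m > med_b,
    )


def enrichment_test(module: GeneSet, de_genes: GeneSet, universe: int) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of the module among DE genes."""
    overlap = len(module.members & de_genes.members)
    set_size, de_size = module.size, de_genes.size
    if universe < len(module.members | de_genes.members):
        raise ValueError("universe smaller than the union of the two sets")
    p = float(stats.hypergeom.sf(overlap - 1, universe, de_size, set_size))
    expected = de_size / universe
    fold = (overlap / set_size) / expected if expected > 0 else float("inf")
    return EnrichmentResult(
        overlap=overlap, set_size=set_size, de_size=de_size, universe=universe,
        fold=float(fold), p_value=p,
    )


def connected_random_subset(
    G: nx.Graph,
    pool: GeneSet,
    size: int,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1000,
) -> GeneSet:
    """Grow a connected random subset of the pool: a random first gene, then
    repeatedly a random pool gene adjacent to the current set.  Dead ends
    restart from a fresh first gene, up to ``max_attempts``."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mapped = sorted(pool.mapped(G))
    if size < 1:
        raise ValueError("size must be >= 1")
    if len(mapped) < size:
        raise ValueError(f"pool has {len(mapped)} mapped genes < size {size}")
    pool_set = set(mapped)
    for _ in range(max_attempts):
        current = {str(rng.choice(mapped))}
        while len(current) < size:
            frontier = sorted(
                {nb for g in current for nb in G[g] if nb in pool_set} - current
            )
            if not frontier:
                break
            current.add(str(rng.choice(frontier)))
        if len(current) == size:
            return GeneSet(name="connected_subset", members=frozenset(current))
    sub = G.subgraph(mapped)
    biggest = max((len(c) for c in nx.connected_components(sub)), default=0)
    raise ValueError(
        f"no connected subset of size {size} found in {max_attempts} attempts "
        f"(largest connected piece of the pool: {biggest})"
    )


def module_vs_connected_random(
    G: nx.Graph,
    module: GeneSet,
    table: DETable,
    size: int = 10,
    n_draws: int = 1000,
    rng_seed: int | None = None,
    p_thresh: float = 0.05,
) -> dict:
    """Connectivity-corrected comparison: distributions of mean |logFC| over
    connected size-g subsets drawn from the module versus from all DE genes."""
    rng = np.random.default_rng(rng_seed)
    df = table.frame.set_index("gene")
    absfc = df["logFC"].abs()
    de_pool = table.de_genes(p_thresh=p_thresh)
    module_pool = GeneSet.from_iterable("module_pool", module.members & set(df.index))

    def draw_means(pool: GeneSet) -> np.ndarray:
        means = np.empty(n_draws)
        for i in range(n_draws):
            subset = connected_random_subset(G, pool, size, rng)
            means[i] = float(absfc.loc[sorted(subset.members)].mean())
        return means

    mod_means = draw_means(module_pool)
    de_means = draw_means(de_pool)
    out = {
        "dataset": table.dataset,
        "size": size,
        "n_draws": n_draws,
        "module_mean": float(mod_means.mean()),
        "de_mean": float(de_means.mean()),
        "module_quantiles": [float(q) for q in np.quantile(mod_means, [0.25, 0.5, 0.75])],
        "de_quantiles": [float(q) for q in np.quantile(de_means, [0.25, 0.5, 0.75])],
    }
    if n_draws > 1:
        _, p = _ranksum(mod_means, de_means)
        out["p_value"] = p
    return out


def overlap_test(module: GeneSet, signature: GeneSet, universe: int) -> EnrichmentResult:
    """Hypergeometric overlap of the module with an annotation signature,
    with the module overlap and signature background as rounded
    percentages."""
    res = enrichment_test(module, signature, universe)
    res.set_percent = round(100 * res.overlap / res.set_size) if res.set_size else 0
    res.background_percent = round(100 * res.de_size / res.universe)
    return res
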