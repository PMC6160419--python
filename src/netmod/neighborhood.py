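"""Seed-anchored network neighborhood: random-walk ranking, association
p-value boundary, component extraction and LCC significance.

The ranking stage scores every gene by a random walk with restart (RWR)
anchored at the seed genes, with transition probabilities proportional to
edge confidence.  Because the raw stationary distribution is biased toward
hubs, each score is divided by the score the same gene attains under the
restart-free walk (whose stationary distribution is proportional to weighted
degree), yielding a degree-adjusted ranking in which a gene is ranked high
only if the seeds pull more probability onto it than its connectivity alone
would.

The neighborhood boundary is chosen from gene-level association p-values:
sliding a window down the ranking, the window's p-values are compared with
the remaining (background) p-values by a one-sided rank-sum test; the
boundary is set where that enrichment plateaus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy import stats

from .interactome import GeneSet

logger = logging.getLogger("netmod")

__all__ = [
    "RankedGene",
    "RankedGeneList",
    "NetworkNeighborhood",
    "LCCSignificance",
    "random_walk_with_restart",
    "degree_adjusted_ranks",
    "plateau_cutoff",
    "build_neighborhood",
    "lcc_significance",
]


@dataclass(frozen=True)
class RankedGene:
    gene: str
    raw_score: float
    adjusted_score: float
    rank: int


@dataclass
class RankedGeneList:
    """Non-seed genes ordered by degree-adjusted RWR score (descending),
    ties broken lexicographically by symbol."""

    entries: list[RankedGene]

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def top(self, k: int) -> list[str]:
        return [e.gene for e in self.entries[:k]]

    def __len__(self) -> int:
        return len(self.entries)

    def to_rows(self) -> list[tuple[str, float, float, int]]:
        return [(e.gene, e.raw_score, e.adjusted_score, e.rank) for e in self.entries]


@dataclass
class NetworkNeighborhood:
    components: list[GeneSet]
    neighborhood: GeneSet
    cutoff_k: int
    seeds_mapped: GeneSet
    seedless: list[GeneSet] = field(default_factory=list)


@dataclass
class LCCSignificance:
    lcc_size: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_rand: int
    seed: int


def _seed_component_nodes(G: nx.Graph, mapped_seeds: set[str]) -> list[str]:
    """Sorted nodes of every connected component containing at least one seed."""
    nodes: set[str] = set()
    for comp in nx.connected_components(G):
        if comp & mapped_seeds:
            nodes |= comp
    return sorted(nodes)


def random_walk_with_restart(
    G: nx.Graph,
    seeds: GeneSet,
    restart: float = 0.75,
    weighted: bool = True,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Stationary distribution of the restart walk anchored at the seeds.

    At each step the walker either restarts (probability ``restart``) at a
    uniformly chosen mapped seed, or moves to a neighbor with probability
    proportional to edge confidence (or uniformly, if ``weighted`` is False).
    The walk is confined to the connected component(s) containing seeds;
    all other nodes score exactly 0.  Scores sum to 1.
    """
    if not 0 < restart < 1:
        raise ValueError(f"restart must be in (0, 1), got {restart}")
    mapped = seeds.mapped(G)
    if not mapped:
        raise ValueError(f"no seed gene maps to the network; unmapped: {sorted(seeds.members)}")
    nodes = _seed_component_nodes(G, set(mapped))
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)

    A = nx.to_scipy_sparse_array(
        G.subgraph(nodes), nodelist=nodes, weight="weight" if weighted else None, format="csr"
    ).astype(float)
    strength = np.asarray(A.sum(axis=1)).ravel()
    # column-stochastic transition operator: P[j, i] = w_ij / strength(i)
    P = (A / strength[:, None]).T.tocsr()

    e = np.zeros(n)
    for g in mapped:
        e[idx[g]] = 1.0 / len(mapped)

    s = e.copy()
    for _ in range(max_iter):
        s_new = restart * e + (1.0 - restart) * (P @ s)
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            break
        s = s_new
    else:  # pragma: no cover - convergence is geometric at rate 1-restart
        raise RuntimeError("random walk failed to converge")

    scores = {g: 0.0 for g in G.nodes}
    for g, i in idx.items():
        scores[g] = float(s[i])
    return scores


def degree_adjusted_ranks(
    G: nx.Graph,
    seeds: GeneSet,
    restart: float = 0.75,
    weighted: bool = True,
) -> RankedGeneList:
    """Rank non-seed genes by degree-adjusted RWR score.

    The restart-free walk's stationary distribution is proportional to
    weighted degree (strength), so the ratio raw/reference removes the hub
    bias of the raw scores entirely -- but over-rewards peripheral
    low-degree genes whose reference score is tiny.  The adjusted score
    merges the two rankings geometrically,

        adjusted(g) = raw(g) / sqrt(reference(g)),

    i.e. the geometric mean of the raw score and the degree-ratio score:
    hubs are demoted by the square root of their degree advantage while the
    raw diffusion signal still carries weight.  Genes outside the seed
    components have zero probability mass and are ranked last with adjusted
    score 0.
    """
    raw = random_walk_with_restart(G, seeds, restart=restart, weighted=weighted)
    mapped = seeds.mapped(G)
    comp_nodes = _seed_component_nodes(G, set(mapped))
    if weighted:
        strength = {g: sum(d.get("weight", 1.0) for d in G[g].values()) for g in comp_nodes}
    else:
        strength = {g: float(G.degree(g)) for g in comp_nodes}
    total = sum(strength.values())
    reference = {g: s / total for g, s in strength.items()}

    adjusted = {}
    for g in G.nodes:
        if g in mapped:
            continue
        ref = reference.get(g, 0.0)
        adjusted[g] = raw[g] / np.sqrt(ref) if ref > 0 else 0.0

    ordered = sorted(adjusted, key=lambda g: (-adjusted[g], g))
    entries = [
        RankedGene(gene=g, raw_score=raw[g], adjusted_score=adjusted[g], rank=i + 1)
        for i, g in enumerate(ordered)
    ]
    return RankedGeneList(entries=entries)


def plateau_cutoff(
    ranked: RankedGeneList,
    pvals: Mapping[str, float],
    window: int = 25,
    alpha: float = 0.05,
    force_k: int | None = None,
    min_coverage: float = 0.8,
    n_perm: int = 200,
) -> int:
    """Boundary of the neighborhood from gene-level association p-values.

    The boundary is estimated as the rank-sum change point: for every
    prefix length k (from ``window`` up to half the ranking) the p-values of
    the top-k genes are compared with the remainder by a one-sided
    Mann-Whitney statistic, and the cutoff is the k with the strongest
    enrichment.  Significance of that strongest split is calibrated by
    permutation of the p-values (``n_perm`` shuffles), so for rankings with
    no association signal the detector returns 0 at level ``alpha``.
    ``force_k`` bypasses detection entirely.
    """
    if force_k is not None:
        return int(force_k)
    if window < 10:
        raise ValueError(f"window must be >= 10, got {window}")
    if len(ranked) < window:
        raise ValueError(f"{len(ranked)} ranked genes < window size {window}")

    covered_p: list[float] = []
    covered_rank_index: list[int] = []  # 0-based position in the full ranking
    n_missing = 0
    for i, entry in enumerate(ranked.entries):
        p = pvals.get(entry.gene)
        if p is None:
            n_missing += 1
            continue
        if not 0 < p <= 1:
            raise ValueError(f"p-value for {entry.gene} outside (0, 1]: {p}")
        covered_p.append(p)
        covered_rank_index.append(i)
    coverage = len(covered_p) / len(ranked)
    if n_missing:
        logger.info("plateau_cutoff: %d ranked gene(s) missing a p-value", n_missing)
    if coverage < min_coverage:
        raise ValueError(f"p-values cover {coverage:.0%} of ranked genes (< {min_coverage:.0%})")

    p_arr = np.asarray(covered_p)
    n = len(p_arr)
    ranks = stats.rankdata(p_arr)
    k_min, k_max = window, n // 2

    def prefix_z(r: np.ndarray) -> np.ndarray:
        # normal-approximation rank-sum z for every prefix split at once:
        # W_k (rank sum of the top k) is a cumulative sum, so all splits
        # cost O(n) together; enrichment toward small p-values gives z << 0
        W = np.cumsum(r)[k_min - 1 : k_max]
        k = np.arange(k_min, k_max + 1)
        mean = k * (n + 1) / 2.0
        sd = np.sqrt(k * (n - k) * (n + 1) / 12.0)
        return (W - mean) / sd

    z = prefix_z(ranks)
    observed = z.min()
    # permutation calibration of the minimum over all splits (the max-split
    # statistic is strongly selective, so a per-split alpha would not hold)
    rng = np.random.default_rng(n_perm * 1_000_003 + n)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = prefix_z(rng.permutation(ranks)).min()
    if observed > np.quantile(null, alpha):
        return 0
    best_k = int(np.argmin(z)) + k_min
    return covered_rank_index[best_k - 1] + 1


def build_neighborhood(
    G: nx.Graph,
    ranked: RankedGeneList,
    seeds: GeneSet,
    cutoff_k: int,
) -> NetworkNeighborhood:
    """Mapped seeds plus the top-k ranked genes, reduced to the connected
    components of the induced subgraph that contain at least one seed.
    Seed-free components are reported separately, not part of the
    neighborhood."""
    if cutoff_k < 0:
        raise ValueError("cutoff_k must be >= 0")
    mapped = seeds.mapped(G)
    candidate = set(mapped) | set(ranked.top(cutoff_k))
    sub = G.subgraph(candidate)
    with_seed: list[GeneSet] = []
    seedless: list[GeneSet] = []
    for i, comp in enumerate(
        sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    ):
        gs = GeneSet(name=f"component_{i + 1}", members=frozenset(comp))
        (with_seed if comp & mapped else seedless).append(gs)
    union = frozenset().union(*(c.members for c in with_seed)) if with_seed else frozenset()
    return NetworkNeighborhood(
        components=with_seed,
        neighborhood=GeneSet(name="neighborhood", members=union),
        cutoff_k=cutoff_k,
        seeds_mapped=GeneSet(name="seeds_mapped", members=mapped),
        seedless=seedless,
    )


def lcc_significance(
    G: nx.Graph,
    genes: GeneSet,
    n_rand: int = 10_000,
    seed: int = 0,
) -> LCCSignificance:
    """Size of the largest connected component induced by ``genes`` versus
    same-sized node sets placed uniformly at random in the network.

    The empirical p-value uses the add-one rule (1 + b) / (1 + n) so that a
    finite sample never reports p = 0.
    """
    mapped = sorted(genes.mapped(G))
    if not mapped:
        raise ValueError("gene set is empty or unmapped")
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")

    def lcc_size(node_subset) -> int:
        sub = G.subgraph(node_subset)
        return max((len(c) for c in nx.connected_components(sub)), default=0)

    observed = lcc_size(mapped)
    rng = np.random.default_rng(seed)
    all_nodes = np.array(sorted(G.nodes), dtype=object)
    null = np.empty(n_rand)
    for i in range(n_rand):
        sample = rng.choice(all_nodes, size=len(mapped), replace=False)
        null[i] = lcc_size(sample)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else 0.0
    emp_p = (1 + int((null >= observed).sum())) / (1 + n_rand)
    return LCCSignificance(
        lcc_size=observed,
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        empirical_p=float(emp_p),
        n_rand=n_rand,
        seed=seed,
    )
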