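"""Confidence-weighted closeness (C_AB): the core statistic.

Distances between genes l, m are minimum-cost paths under per-edge cost

    len(u, v) = ln(p / w_uv),          w_uv in (0, 1],  p >= 1,

so a path's cost is  L*ln(p) - ln(prod w)  for a path of L edges.  The
parameter p tunes the trade-off between hop count and edge confidence:

* p = 1:   cost = -ln(prod w); only confidences matter.  If the w are read
  as independent edge-existence probabilities, the minimum-cost path is the
  most probable path.
* large p: cost ~ L*ln(p); only topology (hop count) matters.

A candidate gene's closeness to a module M is its mean distance to the
reachable members of M, Z-scored against the same quantity for randomly
drawn network nodes:  Z = (observed - mean_null) / sd_null.  Candidates with
Z at or below the threshold (default -1.6, i.e. closer than chance at
p < 0.05 under a normal null) are called significantly close.  The same
randomization applied to the mean pairwise distance within a gene set gives
a set-cohesion Z-score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .interactome import GeneSet

logger = logging.getLogger("netmod")

__all__ = [
    "CabParams",
    "DistanceResult",
    "SetDistance",
    "ClosenessResult",
    "CohesionResult",
    "edge_length",
    "min_weighted_distance",
    "set_distance",
    "closeness_zscore",
    "score_candidates",
    "cohesion_zscore",
]

DEFAULT_P_GRID: tuple[float, ...] = (1.0, math.e, math.e**2, math.e**10)


@dataclass
class CabParams:
    """Parameters of the weighted-closeness statistic."""

    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    reporting_p: float = math.e
    n_rand: int = 10_000
    z_threshold: float = -1.6
    rng_seed: int = 0
    reduce: str = "mean"  # "mean" or "sum" over module members
    degree_binned: bool = False

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.p_grid):
            raise ValueError("every p must be >= 1")
        if self.n_rand < 100:
            raise ValueError("n_rand must be >= 100")
        if self.reduce not in ("mean", "sum"):
            raise ValueError("reduce must be 'mean' or 'sum'")


@dataclass
class DistanceResult:
    source: str
    target: str
    length: float  # +inf when unreachable
    hops: int
    path: list[str]


@dataclass
class SetDistance:
    source: str
    target_set: GeneSet
    mean_length: float
    n_reachable: int
    n_unreachable: int


@dataclass
class ClosenessResult:
    candidate: str
    p: float
    observed: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    significant: bool


@dataclass
class CohesionResult:
    gene_set: GeneSet
    observed_mean_pairwise: float
    null_mean: float
    null_sd: float
    z: float
    n_rand: int


def edge_length(w: float, p: float) -> float:
    """Per-edge cost ln(p / w); nonnegative for w <= 1 <= p."""
    if not 0 < w <= 1:
        raise ValueError(f"confidence must be in (0, 1], got {w}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    return math.log(p) - math.log(w)


def _weight_fn(p: float):
    log_p = math.log(p)

    def fn(u, v, data) -> float:
        return log_p - math.log(data.get("weight", 1.0))

    return fn


def min_weighted_distance(G: nx.Graph, source: str, target: str, p: float = math.e) -> DistanceResult:
    """Minimum-cost path between two genes under ln(p/w) edge costs.

    Among equal-cost shortest paths, the lexicographically smallest node
    sequence is returned (deterministic tie-break).
    """
    for g in (source, target):
        if g not in G:
            raise ValueError(f"unknown gene: {g}")
    if source == target:
        return DistanceResult(source, target, 0.0, 0, [source])
    wfn = _weight_fn(p)
    dist_from_target = nx.single_source_dijkstra_path_length(G, target, weight=wfn)
    if source not in dist_from_target:
        return DistanceResult(source, target, math.inf, 0, [])
    total = dist_from_target[source]
    # greedy reconstruction: at each node pick the smallest-symbol neighbor
    # still on some shortest path, yielding the lexicographic-min sequence
    path = [source]
    node = source
    remaining = total
    tol = 1e-9
    while node != target:
        nxt = None
        for v in sorted(G[node]):
            d_v = dist_from_target.get(v)
            if d_v is None:
                continue
            if abs(wfn(node, v, G[node][v]) + d_v - remaining) <= tol * max(1.0, remaining):
                nxt = v
                break
        assert nxt is not None, "shortest-path reconstruction failed"
        remaining -= wfn(node, nxt, G[node][nxt])
        path.append(nxt)
        node = nxt
    return DistanceResult(source, target, float(total), len(path) - 1, path)


def _lengths_to_set(
    G: nx.Graph, source: str, targets: Sequence[str], p: float
) -> tuple[list[float], int]:
    """(reachable lengths, #unreachable) from source to targets, self excluded."""
    dist = nx.single_source_dijkstra_path_length(G, source, weight=_weight_fn(p))
    lengths, n_unreachable = [], 0
    for t in targets:
        if t == source:
            continue
        if t in dist:
            lengths.append(dist[t])
        else:
            n_unreachable += 1
    return lengths, n_unreachable


def set_distance(
    G: nx.Graph,
    source: str,
    target_set: GeneSet,
    p: float = math.e,
    reduce: str = "mean",
) -> SetDistance:
    """Distance from one gene to a gene set: mean (default) or sum of
    shortest-path lengths over reachable members, the source itself and
    unreachable members excluded."""
    if source not in G:
        raise ValueError(f"unknown gene: {source}")
    targets = sorted(target_set.mapped(G))
    if not targets:
        raise ValueError("target set has no member mapped to the network")
    lengths, n_unreach = _lengths_to_set(G, source, targets, p)
    if not lengths:
        raise ValueError(f"no member of {target_set.name!r} is reachable from {source}")
    value = float(np.sum(lengths)) if reduce == "sum" else float(np.mean(lengths))
    return SetDistance(
        source=source,
        target_set=target_set,
        mean_length=value,
        n_reachable=len(lengths),
        n_unreachable=n_unreach,
    )


def _reduce(lengths: list[float], reduce: str) -> float:
    return float(np.sum(lengths)) if reduce == "sum" else float(np.mean(lengths))


def _null_set_distances(
    G: nx.Graph,
    module_nodes: Sequence[str],
    pool: Sequence[str],
    n_rand: int,
    rng: np.random.Generator,
    p: float,
    reduce: str,
) -> np.ndarray:
    """Set distances for n_rand nodes drawn uniformly (with replacement) from
    the pool.  Draws that cannot reach any module member are redrawn, with a
    cap on total attempts; per-node results are cached since draws repeat."""
    pool_arr = np.asarray(pool, dtype=object)
    out = np.empty(n_rand)
    cache: dict[str, float] = {}
    i = 0
    n_attempts = 0
    while i < n_rand:
        r = str(rng.choice(pool_arr))
        n_attempts += 1
        if n_attempts > 50 * n_rand:
            raise ValueError("null sampling failed: random nodes cannot reach the module")
        if r in cache:
            val = cache[r]
            if math.isnan(val):
                continue
            out[i] = val
            i += 1
            continue
        lengths, _ = _lengths_to_set(G, r, module_nodes, p)
        val = _reduce(lengths, reduce) if lengths else math.nan
        cache[r] = val
        if math.isnan(val):
            continue
        out[i] = val
        i += 1
    return out


def _zscore(observed: float, null: np.ndarray) -> tuple[float, float, float, float]:
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate null distribution (sd = 0)")
    z = (observed - mean) / sd
    emp_p = (1 + int((null <= observed).sum())) / (1 + len(null))
    return mean, sd, float(z), float(emp_p)


def closeness_zscore(
    G: nx.Graph,
    candidate: str,
    module: GeneSet,
    params: CabParams | None = None,
) -> list[ClosenessResult]:
    """Z-score of a candidate's distance-to-module versus random nodes, one
    result per p in the parameter grid."""
    params = params or CabParams()
    if candidate in module:
        raise ValueError(f"candidate {candidate} is inside the module")
    if candidate not in G:
        raise ValueError(f"unknown gene: {candidate}")
    module_nodes = sorted(module.mapped(G))
    if not module_nodes:
        raise ValueError("module has no member mapped to the network")
    pool = _null_pool(G, module_nodes, candidate if params.degree_binned else None)
    results = []
    for p_i, p in enumerate(params.p_grid):
        rng = np.random.default_rng(_derive_seed(params.rng_seed, p_i))
        lengths, _ = _lengths_to_set(G, candidate, module_nodes, p)
        if not lengths:
            raise ValueError(f"candidate {candidate} cannot reach the module")
        observed = _reduce(lengths, params.reduce)
        null = _null_set_distances(G, module_nodes, pool, params.n_rand, rng, p, params.reduce)
        mean, sd, z, emp_p = _zscore(observed, null)
        results.append(
            ClosenessResult(
                candidate=candidate,
                p=p,
                observed=observed,
                null_mean=mean,
                null_sd=sd,
                z=z,
                empirical_p=emp_p,
                significant=z <= params.z_threshold,
            )
        )
    return results


def _derive_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1_000_003 + offset) % (2**31 - 1)


def _null_pool(
    G: nx.Graph, module_nodes: Sequence[str], match_degree_of: str | None
) -> list[str]:
    """Nodes eligible as random stand-ins: non-module nodes, optionally
    restricted to the log2-degree bin of a reference gene."""
    non_module = [g for g in sorted(G.nodes) if g not in set(module_nodes)]
    if match_degree_of is None:
        return non_module
    ref_bin = int(math.log2(max(G.degree(match_degree_of), 1)))
    binned = [g for g in non_module if int(math.log2(max(G.degree(g), 1))) == ref_bin]
    return binned if len(binned) >= 10 else non_module


def score_candidates(
    G: nx.Graph,
    candidates: GeneSet,
    module: GeneSet,
    params: CabParams | None = None,
) -> tuple[list[ClosenessResult], GeneSet, GeneSet]:
    """Score every mapped candidate against the module at every p in the grid.

    Returns (all results sorted by z ascending, the significant subset at the
    reporting p, unmapped candidates).  The random-node null does not depend
    on the candidate, so it is computed once per p and shared.  Candidates in
    the module are excluded; candidates unable to reach the module are
    reported with the unmapped set (unreachable-by-topology).
    """
    params = params or CabParams()
    module_nodes = sorted(module.mapped(G))
    if not module_nodes:
        raise ValueError("module has no member mapped to the network")
    mapped = sorted(candidates.mapped(G) - module.members)
    unmapped = set(candidates.members) - set(mapped)
    results: list[ClosenessResult] = []
    significant: set[str] = set()
    for p_i, p in enumerate(params.p_grid):
        rng = np.random.default_rng(_derive_seed(params.rng_seed, p_i))
        if not params.degree_binned:
            pool = _null_pool(G, module_nodes, None)
            null = _null_set_distances(G, module_nodes, pool, params.n_rand, rng, p, params.reduce)
        for cand in mapped:
            lengths, _ = _lengths_to_set(G, cand, module_nodes, p)
            if not lengths:
                unmapped.add(cand)
                continue
            observed = _reduce(lengths, params.reduce)
            if params.degree_binned:
                pool = _null_pool(G, module_nodes, cand)
                null = _null_set_distances(
                    G, module_nodes, pool, params.n_rand, rng, p, params.reduce
                )
            mean, sd, z, emp_p = _zscore(observed, null)
            res = ClosenessResult(
                candidate=cand,
                p=p,
                observed=observed,
                null_mean=mean,
                null_sd=sd,
                z=z,
                empirical_p=emp_p,
                significant=z <= params.z_threshold,
            )
            results.append(res)
            if res.significant and math.isclose(p, params.reporting_p):
                significant.add(cand)
    results.sort(key=lambda r: (r.z, r.candidate))
    if unmapped:
        logger.info("score_candidates: %d candidate(s) unmapped or unreachable", len(unmapped))
    return (
        results,
        GeneSet(name="significant", members=frozenset(significant)),
        GeneSet(name="unmapped", members=frozenset(unmapped)),
    )


def cohesion_zscore(
    G: nx.Graph,
    gene_set: GeneSet,
    params: CabParams | None = None,
    p: float | None = None,
) -> CohesionResult:
    """Are the genes of a set closer to each other than a random same-sized
    set of network nodes?  Observed statistic: mean pairwise minimum weighted
    distance over reachable pairs; null: the same for uniformly sampled node
    sets of equal size."""
    params = params or CabParams()
    p = params.reporting_p if p is None else p
    mapped = sorted(gene_set.mapped(G))
    if len(mapped) < 2:
        raise ValueError(f"need >= 2 mapped genes, got {len(mapped)}")

    def mean_pairwise(members: Sequence[str]) -> float:
        wfn = _weight_fn(p)
        member_set = set(members)
        lengths = []
        for g in members:
            dist = nx.single_source_dijkstra_path_length(G, g, weight=wfn)
            lengths.extend(d for t, d in dist.items() if t in member_set and t > g)
        if not lengths:
            raise ValueError("no pair of the set is connected")
        return float(np.mean(lengths))

    observed = mean_pairwise(mapped)
    rng = np.random.default_rng(_derive_seed(params.rng_seed, 97))
    all_nodes = np.array(sorted(G.nodes), dtype=object)
    null = np.empty(params.n_rand)
    for i in range(params.n_rand):
        sample = [str(g) for g in rng.choice(all_nodes, size=len(mapped), replace=False)]
        try:
            null[i] = mean_pairwise(sample)
        except ValueError:
            null[i] = math.nan
    null = null[~np.isnan(null)]
    if len(null) < params.n_rand // 2:
        raise ValueError("null sampling failed: too many disconnected random sets")
    mean, sd, z, _ = _zscore(observed, null)
    return CohesionResult(
        gene_set=gene_set,
        observed_mean_pairwise=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        n_rand=params.n_rand,
    )
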