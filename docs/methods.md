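# Methods

## Model and assumptions

The package operates on an undirected interactome whose nodes are uppercased
gene symbols and whose edges carry a confidence `w ∈ (0, 1]`. Edges with
`w = 0` are dropped at load time: under the distance model below they have
infinite length, which is indistinguishable from absence. Duplicate edges
keep the maximum confidence (conservative toward the strongest evidence,
and deterministic); self-loops are dropped with a logged count. The central
assumption throughout is the local-impact hypothesis: genes contributing to
the same disease concentrate in a well-localized region of the interactome,
so proximity to known disease genes is evidence of involvement.

## Random-walk ranking and degree adjustment

Gene scores are the stationary distribution of a restart walk: with
probability `r` (default 0.75, a common restart convention; exposed in every
interface) the walker jumps to a uniformly chosen mapped seed, otherwise it
moves to a neighbor with probability proportional to edge confidence (an
`--unweighted` switch ignores confidences; whether the original analyses
used the weighted or unweighted topology is not determinable, so both are
supported). The walk is confined to the connected component(s) containing
seeds; other nodes score exactly 0. The fixed point is found by power
iteration to an L1 residual below 1e−12 (convergence is geometric at rate
`1 − r`); a dense linear solve serves as the test oracle.

Raw stationary scores are hub-biased: without restart the stationary
distribution is proportional to weighted degree. The adjusted score is

    adjusted(g) = raw(g) / sqrt(reference(g)),

the geometric mean of the raw score and the raw/reference ratio. The pure
ratio was evaluated and rejected: dividing by the full reference score
over-rewards peripheral low-degree genes (whose reference is tiny) and in
synthetic benchmarks demoted half of the planted module below
seed-adjacent bystander genes, while the raw ranking retains full hub bias.
The square-root form demotes a hub by the square root of its degree
advantage while letting the diffusion signal carry weight; on the synthetic
conditions described below it places 14–21 of 22 planted non-seed module
genes in the top 30, versus 8–16 for the full ratio. Seeds are excluded
from the output; ties break lexicographically; genes in seed-free
components rank last with score 0.

## Boundary detection (association-signal change point)

Given gene-level association p-values, the neighborhood boundary is the
point in the ranking where enrichment for small p-values ends. This is
estimated as a rank-sum change point: for every prefix length `k` from
`window` (default 25, the smallest boundary considered) to half the
ranking, the one-sided Mann–Whitney z-statistic of "top-k p-values smaller
than the rest" is computed — all prefixes together cost O(n) because the
prefix rank sum is a cumulative sum — and the cutoff is the `k` minimizing
the statistic. Because the minimum over hundreds of correlated splits is
strongly selective, its significance is calibrated by permutation: the
p-values are shuffled 200 times, the minimum statistic recomputed, and the
observed minimum must fall below the `alpha` (default 0.05) quantile of
that null, otherwise the cutoff is 0. Sliding-window variants (test one
window against the remainder, take the last significant window) were
evaluated and rejected: taking the last significant window anywhere chases
the ~`alpha` fraction of falsely significant windows deep into the tail,
and stopping at the first non-significant window truncates on weak
interleaved signal. On a benchmark with 50 enriched genes
(p ~ Beta(0.2, 1)) ranked above 350 uniform ones, the change-point detector
lands in [40, 75] in 100/100 replicates (median 50) with an exact 5%
false-detection rate on uniform p-values. Genes missing a p-value are
skipped with a logged count (at least 80% coverage required); `--force-k`
bypasses detection for fixed published cutoffs.

The neighborhood is then the union of seed-containing connected components
among seeds plus top-k genes; seed-free components are reported separately.
Localization is quantified by comparing the observed largest connected
component against `n_rand` uniformly sampled same-size node sets (no degree
matching — plain uniform placement — with the empirical p-value using the
add-one rule `(1 + b)/(1 + n)` so finite sampling never reports zero).

## Weighted closeness

Distances between genes use per-edge costs `ln(p / w)` with `p ≥ 1`, so a
path of `L` edges costs `L ln p − ln Π w`. All costs are nonnegative, so
Dijkstra applies; among equal-cost paths the lexicographically smallest
node sequence is chosen (deterministic reconstruction from the target-side
distance tree). The node-to-set distance is the mean over reachable
members of the target set, the source itself excluded; a `--sum` switch
restores the plain sum (with a fixed target set and no unreachable members
the two differ by a constant factor and give identical z-scores, but the
mean is robust when some members are unreachable). Unreachable members are
counted and excluded. The candidate z-score compares the observed
node-to-set distance with that of `n_rand` (default 10,000) nodes drawn
uniformly with replacement from the non-module nodes; the null does not
depend on the candidate and is shared across candidates (identical
statistics, large speedup). An optional degree-binned null draws stand-ins
from the candidate's log2-degree bin, at per-candidate cost. The default
significance rule is `Z ≤ −1.6` (≈ the 5% normal quantile; configurable,
e.g. to −1.645), with the empirical p-value reported alongside because the
normal approximation can be poor in small or very regular networks; a
degenerate null (SD = 0) is an error, not a call. The full grid
`p ∈ {e⁰, e¹, e², e¹⁰}` is always evaluated; significance calls are taken
at the reporting value `p = e`, which balances hop count and confidence.
Set cohesion applies the same randomization to the mean pairwise distance
within a gene set, against uniformly sampled same-size node sets.

Local Radiality — the mean unweighted hop distance from a candidate to the
module, self included when the candidate is a member, unreachable members
excluded — is provided as the topological comparator, together with a
Mann–Whitney comparison of the degree distributions of two candidate sets
(exact enumeration for small tie-free samples, asymptotic otherwise).

## Module assembly

Terminals are the neighborhood genes plus the significant candidates.
Starting from the connected components they induce, the two components
joined by the cheapest path under the same `ln(p/w)` costs are merged
(ties broken by lexicographically smallest path) until one component
remains; a minimum spanning tree of the merged node set is then pruned of
non-terminal leaves, so every surviving linker lies on a tree path between
terminals. This is the classical component-merging family with a 2×
approximation guarantee, verified against an exhaustive-search oracle on
small instances. Terminals split across interactome components are
assembled per component with a warning. Steiner costs default to the same
`p` as scoring; `--hops` switches to unweighted costs.

## Expression validation

DE tables are limma-style TSVs (gene, logFC, P.Value, adj.P.Val;
case-insensitive aliases accepted; duplicate genes collapse to the
smallest-p row). The fold-change comparison rank-sum-tests |logFC| of DE
module genes against DE non-module genes, both filtered at unadjusted
p < 0.05 (per-table candidate reporting uses adjusted p < 0.05; both
thresholds configurable); tests are two-sided, exact below n = 20 without
ties and normal-approximated otherwise. Enrichment uses the one-sided
hypergeometric tail with the universe defaulting to the genes present in
the DE table (expression platforms measure a subset of the interactome;
the interactome size can be passed instead). The connectivity-corrected
control grows connected random subsets — first gene uniform, each next
gene uniform among pool genes adjacent to the current set, restarting on
dead ends up to a bounded number of attempts — from the module and from
all DE genes, and compares the distributions of subset mean |logFC|.
Signature overlap reports the hypergeometric p with module and background
percentages rounded to integers. A `--drop-seeds` flag repeats validation
with seed genes removed, for sensitivity to the anchoring set.

## Synthetic data: what it emulates, and what it does not

The generator produces a preferential-attachment backbone (growth seeded
from an m-clique, so `|E| = C(m,2) + (n−m)·m`) with confidences
`0.05 + 0.95·Beta(2, 2)` — spread over (0, 1] so the p-grid behavior is
exercised, kept away from 0 where edges become meaningless. Into it is
planted a module: a random node subset densified with confidence ≥ 0.8
edges to a target induced density, with a subset designated as seeds.
Association p-values are Beta(a, 1) on module genes (default a = 0.2) and
uniform elsewhere; pull-down partners are non-module, non-adjacent nodes of
which a fraction (default 9/96) is wired to ≥ 3 module genes at confidence
≥ 0.8; DE tables draw background logFC from N(0, 1) and module logFC from
N(±fc_effect, 1) (default effect 2), with p-values from a two-sided z-test
of the drawn value and Benjamini–Hochberg adjustment. Defaults — 400
genes, attachment 3, module 30, density 0.3, 8 seeds, 96 partners —
scale the real use case (a ~14k-gene interactome, a 150-gene neighborhood,
~10 seeds) down to desk size while keeping each stage's statistical
structure intact. Every generator is deterministic given `rng_seed`.

What passing tests on these fixtures show: the distance and assembly
machinery is exact (oracle-verified), the randomization z-scores are
calibrated, and each stage detects the kind of signal it assumes, at
realistic signal-to-noise. What they do not show: performance on real
interactomes, whose degree correlations, clustering and confidence
structure a preferential-attachment backbone does not reproduce, and
robustness to systematic ascertainment bias in interaction databases,
which no resampling null can capture.

## Numerical choices and degenerate inputs

Power iteration stops at L1 residual 1e−12; shortest-path tie-breaks use a
relative tolerance of 1e−9 when testing whether an edge lies on a shortest
path; empirical p-values use the add-one rule; per-stage RNG streams are
derived from the global seed as `(seed · 1000003 + stage) mod (2³¹ − 1)` so
stage-level reruns are reproducible. Degenerate inputs are errors with
specific messages rather than silent results: empty graphs, unmapped seed
sets, candidates inside the module, all-unreachable target sets, null
distributions with zero variance, fewer than 3 DE genes on either side of
the fold-change comparison, and connected-subset pools that cannot support
the requested size.

## Known limitations

The boundary detector assumes a single enriched head; multi-modal
enrichment profiles yield the strongest single split. The greedy Steiner
heuristic guarantees only a 2× cost bound, and linker identities can be
sensitive to confidence perturbations even when module membership is
stable. Cohesion and closeness nulls sample nodes uniformly by default;
in networks with heavy-tailed degree distributions a degree-binned null
(provided as an option) is the more conservative choice. At the default
test scale (hundreds of nodes) empirical p-values bottom out at
`1/(1 + n_rand)`; genome-scale runs should raise `n_rand`.
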