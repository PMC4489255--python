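# Methods

## Problem and model

`subnetx` infers, from a genome-wide typed interaction network and a
differential-expression experiment, the edge subset that best explains
how a list of prioritized genes is connected. The model has three
layers:

1. **Probabilistic network.** Log fold changes are modelled as draws
   from a single normal distribution N(μ, σ) fitted to the whole
   expression table. A gene's score, |1 − 2·Φ<sub>(μ,σ)</sub>(D)|, is
   one minus its two-tailed normal p-value: 0 at the distribution
   centre, approaching 1 in either tail. An edge's presence
   probability is the product of its endpoint scores, so an edge is
   likely "on" only when both partners respond to the condition.
   Genes without a measurement score 0.5, a neutral prior that neither
   promotes nor kills the incident edges.

2. **Mode-valid k-best paths.** Connectivity between list genes is
   carried by acyclic paths of 2–5 edges. Downstream paths may not
   traverse a directed edge backwards. Upstream paths consist of a
   nonempty prefix traversed against edge direction (up to a common
   regulator) and a nonempty suffix traversed forwards, both terminal
   edges having a regulatory interaction type; undirected edges are
   free in either segment. Exact two-terminal network reliability is
   NP-hard, so connectivity is approximated over the k most probable
   valid paths per ordered gene pair, found by bounded depth-first
   enumeration (complete at these path lengths) with a per-pair heap.

3. **Objective and optimizer.** The selected sub-network S maximizes
   O(S) = Σ_A P(path(A,·)|S) − x_c·|S|, where the first term sums over
   start genes the exact probability that at least one of A's retained
   paths survives inside S, and x_c prices each selected edge.

## Exact union probability

Each physical edge is one independent Bernoulli(P_edge) variable shared
by every path that uses it, so the path-survival events are dependent
and the naive independent-paths formula is wrong. The union
probability is computed exactly by conditioning (Shannon expansion) on
the most shared edge, with three engineering choices that matter at
optimizer scale: edges are mapped to bits so path edge sets are machine
integers; families of at most 6 events are evaluated by direct
inclusion–exclusion with a subset-DP that reuses partial products; and
absorption (dropping a path whose edge set contains another's) is
applied once per query, with plain deduplication inside the recursion.
Results are memoised per start gene across the whole optimization. A
2<sup>m</sup> brute-force enumerator over edge states serves as an
independent test oracle and agrees to 1e−9 on randomized instances.

## Greedy hill climbing

The climber starts from the empty sub-network. Its move set is
(a) *path completion* — add all still-missing edges of one retained
path in a single move — and (b) *single-edge removal*. Pure
single-edge additions cannot serve as the only addition move: every
path spans at least two edges, so from the empty set no single edge
creates connectivity and the climb could never start; a single-edge
addition that does complete a path is exactly a path-completion move of
size one. Each iteration applies the strictly-improving move with the
largest exact gain; the returned S is therefore stable against every
path completion, every single-edge addition and every single-edge
removal, which the test suite verifies by full recomputation. Gains
below 1e−12 are treated as zero to keep floating-point noise from
cycling.

Two exactness-preserving accelerations: the candidate universe is
restricted to edges on retained paths (any other edge adds penalty but
no connectivity — provable, and tested); and candidates are evaluated
lazily in order of a cheap upper bound (the union bound over newly
completed paths, capped by each start gene's headroom 1 − conn(A)),
with exact evaluation stopping once no remaining bound can beat or tie
the best exact gain. Ties break on the lexicographically smallest edge
tuple, so runs are fully deterministic. The incremental objective is
cross-checked against a full recomputation at termination.

Greedy hill climbing is a local search: on small instances where
exhaustive subset search is feasible the suite reports the gap to the
global optimum (typically zero on those toys), but no global guarantee
is made.

## Parameters

| parameter | default | range | meaning |
|---|---|---|---|
| `mode` | — | upstream / downstream | path semantics (see above) |
| `cost` (x_c) | — | ≥ 0 | price per selected edge; higher = sparser |
| `max_path_length` | 4 | 2–5 | maximum edges per path |
| `k` | 10 | 5–50 | retained paths per ordered gene pair |
| `regulatory_types` | {pd, srna} | — | accepted upstream terminal types |
| `k_scope` | pair | pair / start | whether k bounds each pair or pools a start gene |

Path length counts interactions (edges). The length and k ranges are
hard limits enforced by `validate_config`; the defaults follow the
parameter choices established for this family of methods. Sweeping
`cost` downward (`cost_sweep`) yields an ordered series of sub-networks
from the sparsest core outward; the mean sub-network size across the
synthetic suite is non-increasing in cost, though greedy search does
not guarantee per-instance monotonicity.

## Synthetic scenarios

The generator emulates the method's intended inputs without any
external download: 200 genes; 2 planted regulator hubs with 20 targets
each wired by directed `pd` edges; an Erdős–Rényi-style background of
120 `pd`, 160 `pp` (undirected) and 80 `met` edges (≈400 edges total,
mean degree ≈4, comparable to a bacterial interactome's density);
target log fold changes drawn from Normal(±3, 1) with a per-regulator
sign and background genes from Normal(0, 1); and a gene list of all
genes with |log fold change| > 1.5, mirroring common
differential-expression cutoffs. A small GAF file annotates each
regulator module so enrichment runs end to end. Everything derives
from one seed and regenerates byte-identically.

What the scenarios do *not* emulate: scale-free interactome topology,
replicate-level count noise and p-value-based gene selection, correlated
regulons, or identifier-mapping problems. Passing the planted-recovery
suite therefore shows the machinery finds strong planted structure
under the stated noise — not that real interactomes are this easy.

Smaller variants (60–80 genes, 8–10 targets per regulator) are used
where a test needs many independent optimizer runs; the standard
200-gene scenario is used for the 20-seed recovery check.

## Numerical and degenerate-input choices

- σ is the sample (n−1) standard deviation; a zero-variance or
  single-gene table is an error ("degenerate expression distribution").
- The normal CDF is evaluated exactly (scipy), not via lookup tables,
  so scores can differ from hand-rounded worked values by ~0.01–0.02.
- No probability floor or ceiling: a zero-probability edge is legal and
  nullifies every path through it; such paths are still retained when
  nothing better exists.
- Self-loops are rejected at load (paths are acyclic, so they could
  never participate); duplicate (source, target, type) lines collapse
  with a warning; parallel edges of different type are distinct
  variables.
- Gene identifiers are case-sensitive exact strings; no synonym
  mapping.
- An upstream path may not degenerate to a single direct regulatory
  edge: prefix and suffix must both be nonempty so the apex is a
  genuine shared regulator, and the minimum path length is 2 in both
  modes.
- In upstream enumeration an undirected edge can belong to either
  segment; duplicate edge sequences reachable under several splits are
  emitted once, with the smallest feasible split recorded.
- Retained paths are fixed once on the full probabilistic network;
  sub-network scoring only re-restricts them (paths become invalid in
  S, they are never re-enumerated per S).

## Enrichment

The enrichment universe is the set of genes in the loaded interaction
network — the frame the sub-network was drawn from. Per term with at
least one sub-network gene the upper-tail hypergeometric p-value
P(X ≥ k | N, K, n) is computed (scipy), with Benjamini–Hochberg
q-values over all tested terms (statsmodels). Annotations are used as
given in the GAF; there is no GO-graph propagation, which understates
the enrichment of general terms. GAF files carry no term names, so
terms display as their identifiers.

## Known limitations

- Connectivity is exact only over the retained k-best paths; genuinely
  parallel weak paths beyond the k-th are invisible to the objective.
- Greedy hill climbing offers local, not global, optimality.
- No statistical significance is attached to the selected sub-network;
  enrichment of the result is reported as a descriptive aid.
- The single-normal model of log fold changes is a pragmatic scoring
  device; heavy-tailed or bimodal expression data will distort scores.
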