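"""Exact probability that at least one retained path survives.

Each edge of the probabilistic network is an independent Bernoulli
variable with success probability ``P_edge``; the same physical edge is
one variable everywhere, shared across paths.  The probability of
connectedness of a start gene given a sub-network S is the probability
of the union of the events "all edges of retained path i are present",
over the retained paths that are still fully inside S.

The union is computed exactly by Shannon expansion: condition on one
shared edge at a time, simplify the surviving path family (absorption:
a path whose edge set contains another's is redundant), and memoise on
the reduced family.  A 2^m brute-force enumerator over edge states is
kept as an independent oracle for testing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

from .graphio import Edge
from .pathfinder import Path
from .probnet import ProbabilisticNetwork

__all__ = [
    "SubNetwork",
    "ConnectivityQuery",
    "UnionEngine",
    "path_probability",
    "restrict_paths",
    "union_probability",
    "brute_force_union",
    "connectivity",
]

#: Safety bound for the brute-force oracle (2^m edge states).
BRUTE_FORCE_MAX_EDGES = 20


@dataclass(frozen=True)
class SubNetwork:
    """An edge subset of the probabilistic network, the optimizer's unit.

    ``extra_nodes`` allows isolated nodes (e.g. a singleton sub-network
    with no edges) to survive serialization.
    """

    edges: FrozenSet[Edge]
    extra_nodes: FrozenSet[str] = frozenset()

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        network: ProbabilisticNetwork | None = None,
        extra_nodes: Iterable[str] = (),
    ) -> "SubNetwork":
        edges = frozenset(edges)
        if network is not None:
            unknown = edges - set(network.edge_probability)
            if unknown:
                raise ValueError(f"{len(unknown)} edge(s) not in the probabilistic network")
        return cls(edges=edges, extra_nodes=frozenset(extra_nodes))

    @property
    def nodes(self) -> FrozenSet[str]:
        endpoints = {n for e in self.edges for n in (e.source, e.target)}
        return frozenset(endpoints | set(self.extra_nodes))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: Edge) -> bool:
        return edge in self.edges


@dataclass(frozen=True)
class ConnectivityQuery:
    """P(path(A, .) | S): start gene, its retained paths, conditioning S."""

    start: str
    paths: Tuple[Path, ...]
    subnetwork: SubNetwork
    network: ProbabilisticNetwork

    def __post_init__(self) -> None:
        for p in self.paths:
            if p.start != self.start:
                raise ValueError(f"path starting at {p.start!r} in query for {self.start!r}")


def path_probability(path: Path, network: ProbabilisticNetwork) -> float:
    """Product of the edge probabilities along the path."""
    prob = 1.0
    for e in path.edges:
        if e not in network.edge_probability:
            raise ValueError(f"edge {e} not in the probabilistic network")
        prob *= network.edge_probability[e]
    return prob


def restrict_paths(paths: Sequence[Path], subnetwork: SubNetwork) -> List[Path]:
    """Keep exactly the paths all of whose edges lie in the sub-network."""
    return [p for p in paths if all(e in subnetwork.edges for e in p.edges)]


def _absorb_masks(family: Iterable[int]) -> FrozenSet[int]:
    """Drop supersets: if mask s ⊆ t then event(t) ⊆ event(s)."""
    masks = sorted(set(family), key=lambda m: (m.bit_count(), m))
    kept: List[int] = []
    for m in masks:
        if not any(k & m == k for k in kept):
            kept.append(m)
    return frozenset(kept)


#: Families at or below this size use direct inclusion-exclusion.
_IE_MAX = 6


def _incl_excl(masks: Sequence[int], bit_probs: Sequence[float]) -> float:
    """Inclusion-exclusion by subset dynamic programming.

    ``or_masks[s]`` extends ``s`` minus its lowest element by one mask;
    the product over the newly covered bits updates the subset term
    incrementally, so each of the 2^n - 1 terms costs only the bits it
    adds.
    """
    n = len(masks)
    size = 1 << n
    or_masks = [0] * size
    prods = [1.0] * size
    bits = [0] * size
    total = 0.0
    for s in range(1, size):
        low = s & -s
        prev = s ^ low
        base = or_masks[prev]
        extra = masks[low.bit_length() - 1] & ~base
        p = prods[prev]
        while extra:
            b = extra & -extra
            p *= bit_probs[b.bit_length() - 1]
            extra ^= b
        or_masks[s] = base | masks[low.bit_length() - 1]
        prods[s] = p
        k = bits[prev] + 1
        bits[s] = k
        total += p if k & 1 else -p
    return total


def _mask_union(
    family: FrozenSet[int],
    bit_probs: Sequence[float],
    memo: Dict[FrozenSet[int], float],
) -> float:
    """Shannon expansion over an absorbed family of edge bitmasks."""
    if not family:
        return 0.0
    if 0 in family:
        return 1.0
    cached = memo.get(family)
    if cached is not None:
        return cached
    if len(family) <= _IE_MAX:
        value = _incl_excl(sorted(family), bit_probs)
        memo[family] = value
        return value
    counts: Dict[int, int] = {}
    for m in family:
        while m:
            b = m & -m
            counts[b] = counts.get(b, 0) + 1
            m ^= b
    cmax = max(counts.values())
    if cmax == 1:
        # No shared edge: events are independent.
        value = 1.0
        for m in family:
            p = 1.0
            while m:
                b = m & -m
                p *= bit_probs[b.bit_length() - 1]
                m ^= b
            value *= 1.0 - p
        value = 1.0 - value
    else:
        # Condition on the most shared edge; smallest bit on ties keeps
        # the recursion deterministic.
        pivot = min(b for b, c in counts.items() if c == cmax)
        p = bit_probs[pivot.bit_length() - 1]
        # Deduplication alone suffices here; the 0-mask check above acts
        # as the termination rule, and full absorption is applied only at
        # the top level where it pays off.
        present = frozenset(m & ~pivot for m in family)
        absent = frozenset(m for m in family if not m & pivot)
        value = p * _mask_union(present, bit_probs, memo) + (1.0 - p) * _mask_union(
            absent, bit_probs, memo
        )
    memo[family] = value
    return value


class UnionEngine:
    """Reusable exact union-probability calculator over a fixed edge set.

    Maps each involved edge to one bit so repeated queries (as in the
    optimizer's move evaluations) share a single memo table.
    """

    def __init__(self, edges: Sequence[Edge], probs: Mapping[Edge, float]):
        self.edges = sorted(set(edges))
        if len(self.edges) > 512:
            # Bitmask arithmetic stays exact at any width; this guards
            # against accidentally feeding the whole network in.
            raise ValueError(f"union engine over {len(self.edges)} edges")
        self.bit = {e: 1 << i for i, e in enumerate(self.edges)}
        self.bit_probs = [probs[e] for e in self.edges]
        self.memo: Dict[FrozenSet[int], float] = {}

    def mask(self, edge_set: Iterable[Edge]) -> int:
        m = 0
        for e in edge_set:
            m |= self.bit[e]
        return m

    def union_masks(self, masks: Iterable[int]) -> float:
        family = _absorb_masks(masks)
        return min(1.0, max(0.0, _mask_union(family, self.bit_probs, self.memo)))

    def union(self, family: Iterable[FrozenSet[Edge]]) -> float:
        return self.union_masks(self.mask(s) for s in family)


def union_family_probability(
    family: Iterable[FrozenSet[Edge]],
    probs: Mapping[Edge, float],
    engine: UnionEngine | None = None,
) -> float:
    """Exact P(at least one edge set fully present), shared-edge aware."""
    family = list(family)
    if engine is None:
        involved = sorted({e for s in family for e in s})
        engine = UnionEngine(involved, probs)
    return engine.union(family)


def union_probability(paths: Sequence[Path], network: ProbabilisticNetwork) -> float:
    """Exact probability that at least one of the paths is fully present.

    Shared edges are handled correctly (this is NOT the product formula
    for independent paths); duplicated paths do not change the result.
    Returns 0 for an empty path list.
    """
    if not paths:
        return 0.0
    family = []
    for p in paths:
        for e in p.edges:
            if e not in network.edge_probability:
                raise ValueError(f"edge {e} not in the probabilistic network")
        family.append(p.edge_set())
    return union_family_probability(family, network.edge_probability)


def brute_force_union(paths: Sequence[Path], network: ProbabilisticNetwork) -> float:
    """Oracle: sum over all 2^m edge-state assignments.

    Only usable when the union of involved edges has at most
    ``BRUTE_FORCE_MAX_EDGES`` members.
    """
    if not paths:
        return 0.0
    involved = sorted({e for p in paths for e in p.edges})
    m = len(involved)
    if m > BRUTE_FORCE_MAX_EDGES:
        raise ValueError(f"oracle scale exceeded: {m} > {BRUTE_FORCE_MAX_EDGES} edges")
    index = {e: i for i, e in enumerate(involved)}
    probs = [network.edge_probability[e] for e in involved]
    masks = [
        sum(1 << index[e] for e in p.edges) for p in paths
    ]
    total = 0.0
    for state in range(1 << m):
        if not any((state & mk) == mk for mk in masks):
            continue
        weight = 1.0
        for i in range(m):
            weight *= probs[i] if (state >> i) & 1 else 1.0 - probs[i]
        total += weight
    return total


def connectivity(query: ConnectivityQuery) -> float:
    """P(path(A, .) | S): union over the paths surviving the restriction."""
    surviving = restrict_paths(list(query.paths), query.subnetwork)
    return union_probability(surviving, query.network)
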