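"""Objective scoring and greedy hill-climbing sub-network selection.

The objective trades connectivity against sparsity:

    O(S) = sum_{A in L} P(path(A, .) | S)  -  x_c * |S|

where the first term sums, over the gene-list start genes, the exact
probability that at least one retained path from A survives inside S,
and the penalty is a constant cost ``x_c`` per selected edge.

The climber starts from the empty sub-network and repeatedly applies
the move with the largest strictly positive objective gain, stopping at
a local optimum.  Moves are (a) completing one retained path by adding
all of its still-missing edges at once and (b) removing one selected
edge.  Path-completion moves are necessary because every path spans at
least two edges: from the empty set no single-edge addition can create
connectivity, so an edge-only move set could never leave the trivial
optimum.  A single-edge addition that completes some path is exactly a
path-completion move with one missing edge, so the returned optimum is
also stable against all single-edge additions and removals.  Ties are
broken on the lexicographically smallest edge tuple, making runs fully
deterministic.  The candidate universe is restricted to edges lying on
at least one retained path: any other edge contributes penalty but no
connectivity, so excluding it is lossless.

Move evaluation is incremental — adding or removing an edge can only
change the connectivity of start genes with a retained path through
that edge — but correctness is defined by full recomputation, which the
returned result is checked against.
"""
from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from itertools import combinations
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .graphio import Edge
from .pathfinder import PathSet, RunConfig, validate_config
from .pathprob import (
    SubNetwork,
    UnionEngine,
    restrict_paths,
    union_probability,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveValue",
    "Move",
    "OptimizationResult",
    "objective",
    "greedy_optimize",
    "is_local_optimum",
    "exhaustive_optimize",
    "cost_sweep",
]

#: Minimum gain treated as a strict improvement (guards against
#: floating-point noise producing endless add/remove cycles).
GAIN_TOLERANCE = 1e-12


@dataclass(frozen=True)
class ObjectiveValue:
    """O(S) split into its connectivity and sparsity-penalty terms."""

    connectivity_term: float
    penalty_term: float

    @property
    def total(self) -> float:
        return self.connectivity_term - self.penalty_term


@dataclass(frozen=True)
class Move:
    op: str  # "add" (one or more edges completing a path) or "remove"
    edges: Tuple[Edge, ...]
    gain: float
    objective_after: float


@dataclass
class OptimizationResult:
    subnetwork: SubNetwork
    objective: ObjectiveValue
    moves: List[Move] = field(default_factory=list)
    cost: float = 0.0


def objective(
    subnetwork: SubNetwork, pathsets: PathSet, config: RunConfig
) -> ObjectiveValue:
    """Full (non-incremental) evaluation of O(S); the correctness reference."""
    cfg = validate_config(config)
    conn = 0.0
    for _start, paths in sorted(pathsets.by_start.items()):
        surviving = restrict_paths(paths, subnetwork)
        conn += union_probability(surviving, pathsets.network)
    penalty = cfg.cost * subnetwork.n_edges
    return ObjectiveValue(connectivity_term=conn, penalty_term=penalty)


class _GreedyState:
    """Incremental bookkeeping for the hill climber.

    For each retained path we track the set of its edges missing from the
    current sub-network; a path is surviving when that set is empty.
    Per-start connectivity values are cached and memoised on the frozen
    set of surviving path indices, so repeated hypothetical evaluations
    of the same move are cheap.
    """

    def __init__(self, pathsets: PathSet, cost: float):
        self.cost = cost
        self.probs = pathsets.network.edge_probability
        self.starts: List[str] = []
        self.path_edges: Dict[str, List[FrozenSet[Edge]]] = {}
        for start, paths in sorted(pathsets.by_start.items()):
            self.starts.append(start)
            self.path_edges[start] = [p.edge_set() for p in paths]
        self.edge_paths: Dict[Edge, List[Tuple[str, int]]] = defaultdict(list)
        self.missing: Dict[Tuple[str, int], Set[Edge]] = {}
        self.path_prob: Dict[Tuple[str, int], float] = {}
        for start in self.starts:
            for i, es in enumerate(self.path_edges[start]):
                self.missing[(start, i)] = set(es)
                prob = 1.0
                for e in es:
                    self.edge_paths[e].append((start, i))
                    prob *= self.probs[e]
                self.path_prob[(start, i)] = prob
        self.rebuild_groups()
        self.universe: List[Edge] = sorted(self.edge_paths)
        self.selected: Set[Edge] = set()
        self.surviving: Dict[str, FrozenSet[int]] = {s: frozenset() for s in self.starts}
        self.conn: Dict[str, float] = {s: 0.0 for s in self.starts}
        # Per start: a bitmask union engine over that start's path edges,
        # plus a memo from surviving path-index sets to probabilities.
        self._engine: Dict[str, UnionEngine] = {}
        self._path_masks: Dict[str, List[int]] = {}
        for start in self.starts:
            edges = sorted({e for es in self.path_edges[start] for e in es})
            engine = UnionEngine(edges, self.probs)
            self._engine[start] = engine
            self._path_masks[start] = [engine.mask(es) for es in self.path_edges[start]]
        self._conn_memo: Dict[str, Dict[FrozenSet[int], float]] = {
            s: {frozenset(): 0.0} for s in self.starts
        }

    def conn_of(self, start: str, surviving: FrozenSet[int]) -> float:
        memo = self._conn_memo[start]
        value = memo.get(surviving)
        if value is None:
            masks = self._path_masks[start]
            value = self._engine[start].union_masks(masks[i] for i in surviving)
            memo[surviving] = value
        return value

    def connectivity_total(self) -> float:
        return sum(self.conn[s] for s in self.starts)

    def rebuild_groups(self) -> None:
        """Group incomplete paths by their (frozen) missing-edge set."""
        self.missing_groups: Dict[FrozenSet[Edge], List[Tuple[str, int]]] = defaultdict(list)
        for key, ms in self.missing.items():
            if ms:
                self.missing_groups[frozenset(ms)].append(key)

    def candidate_additions(self) -> List[FrozenSet[Edge]]:
        """Distinct missing-edge sets of the not-yet-surviving paths."""
        return sorted(self.missing_groups, key=lambda s: tuple(sorted(s)))

    def _newly_surviving(self, added: FrozenSet[Edge]) -> Dict[str, List[int]]:
        # Paths completed by adding ``added`` are those whose missing set
        # is a nonempty subset; missing sets are at most max_path_length
        # edges, so enumerate the subsets of ``added`` directly.
        newly: Dict[str, List[int]] = defaultdict(list)
        items = sorted(added)
        for r in range(1, len(items) + 1):
            for combo in combinations(items, r):
                for start, i in self.missing_groups.get(frozenset(combo), ()):
                    newly[start].append(i)
        return newly

    def gain_add_bound(self, added: FrozenSet[Edge]) -> float:
        """Cheap upper bound on the addition gain.

        Per affected start the connectivity increase is at most the union
        bound over the newly completed paths and at most the headroom to
        certain connectivity, ``1 - conn``.
        """
        total = 0.0
        for start, idxs in self._newly_surviving(added).items():
            s = 0.0
            for i in idxs:
                s += self.path_prob[(start, i)]
            total += min(s, 1.0 - self.conn[start])
        return total - self.cost * len(added)

    def gain_add(self, added: FrozenSet[Edge]) -> float:
        delta = 0.0
        for start, idxs in self._newly_surviving(added).items():
            new_set = self.surviving[start] | frozenset(idxs)
            delta += self.conn_of(start, new_set) - self.conn[start]
        return delta - self.cost * len(added)

    def gain_remove(self, edge: Edge) -> float:
        delta = 0.0
        dying: Dict[str, List[int]] = defaultdict(list)
        for start, i in self.edge_paths[edge]:
            if not self.missing[(start, i)]:
                dying[start].append(i)
        for start, idxs in dying.items():
            new_set = self.surviving[start] - frozenset(idxs)
            delta += self.conn_of(start, new_set) - self.conn[start]
        return delta + self.cost

    def apply(self, op: str, edges: Tuple[Edge, ...]) -> None:
        touched: Set[str] = set()
        if op == "add":
            for edge in edges:
                if edge in self.selected:
                    continue
                self.selected.add(edge)
                for start, i in self.edge_paths[edge]:
                    ms = self.missing[(start, i)]
                    ms.discard(edge)
                    if not ms:
                        self.surviving[start] = self.surviving[start] | {i}
                        touched.add(start)
        else:
            (edge,) = edges
            self.selected.discard(edge)
            for start, i in self.edge_paths[edge]:
                ms = self.missing[(start, i)]
                if not ms:
                    self.surviving[start] = self.surviving[start] - {i}
                    touched.add(start)
                ms.add(edge)
        for start in touched:
            self.conn[start] = self.conn_of(start, self.surviving[start])
        self.rebuild_groups()


def greedy_optimize(pathsets: PathSet, config: RunConfig) -> OptimizationResult:
    """Best-improvement hill climbing from the empty sub-network.

    Each iteration evaluates every single-edge addition from the
    candidate universe and every removal from the current selection,
    applies the best strictly improving move, and stops when none
    remains.  Fully deterministic (lexicographic tie-breaking).
    """
    cfg = validate_config(config)
    state = _GreedyState(pathsets, cfg.cost)
    moves: List[Move] = []
    if not state.universe:
        logger.warning("candidate edge universe is empty; returning empty sub-network")
        empty = SubNetwork(edges=frozenset())
        return OptimizationResult(
            subnetwork=empty,
            objective=objective(empty, pathsets, cfg),
            moves=moves,
            cost=cfg.cost,
        )
    while True:
        best: Optional[Tuple[float, Tuple[Edge, ...], str]] = None

        def better(gain: float, edges: Tuple[Edge, ...]) -> bool:
            if gain <= GAIN_TOLERANCE:
                return False
            if best is None:
                return True
            if gain > best[0] + GAIN_TOLERANCE:
                return True
            return abs(gain - best[0]) <= GAIN_TOLERANCE and edges < best[1]

        # Lazy evaluation: the union bound over newly completed paths
        # upper-bounds the exact gain, so candidates are processed in
        # bound order and evaluation stops once no remaining bound can
        # beat (or tie) the best exact gain found.
        scored = []
        for added in state.candidate_additions():
            bound = state.gain_add_bound(added)
            if bound > GAIN_TOLERANCE:
                scored.append((bound, tuple(sorted(added)), added))
        scored.sort(key=lambda t: (-t[0], t[1]))
        for bound, edges, added in scored:
            if best is not None and bound < best[0] - GAIN_TOLERANCE:
                break
            gain = state.gain_add(added)
            if better(gain, edges):
                best = (gain, edges, "add")
        for e in sorted(state.selected):
            gain = state.gain_remove(e)
            if better(gain, (e,)):
                best = (gain, (e,), "remove")
        if best is None:
            break
        gain, edges, op = best
        state.apply(op, edges)
        total = state.connectivity_total() - cfg.cost * len(state.selected)
        moves.append(Move(op=op, edges=edges, gain=gain, objective_after=total))
    sub = SubNetwork(edges=frozenset(state.selected))
    obj = objective(sub, pathsets, cfg)
    # The incremental trace and the full recomputation must agree.
    if moves and abs(obj.total - moves[-1].objective_after) > 1e-6:
        raise AssertionError(
            "incremental objective diverged from full recomputation: "
            f"{moves[-1].objective_after} vs {obj.total}"
        )
    return OptimizationResult(subnetwork=sub, objective=obj, moves=moves, cost=cfg.cost)


def is_local_optimum(
    result: OptimizationResult, pathsets: PathSet, config: RunConfig
) -> bool:
    """Verify by full recomputation that no move improves O(S).

    Checks every single-edge addition and removal and every
    path-completion addition against the climber's move set.
    """
    cfg = validate_config(config)
    base = objective(result.subnetwork, pathsets, cfg).total
    selected = result.subnetwork.edges
    candidates: Set[FrozenSet[Edge]] = set()
    for e in sorted(pathsets.all_edges()):
        if e in selected:
            candidates.add(frozenset())  # placeholder, removals handled below
        else:
            candidates.add(frozenset({e}))
    candidates.discard(frozenset())
    for paths in pathsets.by_pair.values():
        for p in paths:
            ms = frozenset(p.edge_set() - selected)
            if ms:
                candidates.add(ms)
    for added in candidates:
        candidate = SubNetwork(edges=selected | added)
        if objective(candidate, pathsets, cfg).total > base + 1e-9:
            return False
    for e in sorted(selected):
        candidate = SubNetwork(edges=selected - {e})
        if objective(candidate, pathsets, cfg).total > base + 1e-9:
            return False
    return True


def exhaustive_optimize(
    pathsets: PathSet, config: RunConfig, max_universe: int = 16
) -> OptimizationResult:
    """Global optimum by enumerating all subsets of the candidate universe.

    Test oracle for small instances only (2^|U| evaluations).
    """
    cfg = validate_config(config)
    universe = sorted(pathsets.all_edges())
    if len(universe) > max_universe:
        raise ValueError(
            f"exhaustive search over {len(universe)} edges exceeds {max_universe}"
        )
    best_sub = SubNetwork(edges=frozenset())
    best_obj = objective(best_sub, pathsets, cfg)
    for mask in range(1, 1 << len(universe)):
        edges = frozenset(e for i, e in enumerate(universe) if (mask >> i) & 1)
        sub = SubNetwork(edges=edges)
        obj = objective(sub, pathsets, cfg)
        if obj.total > best_obj.total + 1e-15:
            best_sub, best_obj = sub, obj
    return OptimizationResult(subnetwork=best_sub, objective=best_obj, cost=cfg.cost)


def cost_sweep(
    pathsets: PathSet, config: RunConfig, costs: Sequence[float]
) -> List[OptimizationResult]:
    """Independent greedy runs over a strictly decreasing cost series.

    Stepwise decreasing the cost yields an ordered series of sub-networks,
    from the sparsest upward.
    """
    if not costs:
        raise ValueError("empty cost list")
    if any(b >= a for a, b in zip(costs, costs[1:])):
        raise ValueError("costs must be strictly decreasing")
    if any(c < 0 for c in costs):
        raise ValueError("costs must be nonnegative")
    results = []
    for c in costs:
        cfg = dataclasses.replace(config, cost=float(c))
        res = greedy_optimize(pathsets, cfg)
        logger.info("cost %.4g -> %d edges, O(S) = %.4f", c, res.subnetwork.n_edges, res.objective.total)
        results.append(res)
    return results
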