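"""Mode-valid path enumeration and k-best retention.

A path is an acyclic sequence of 2 to ``max_path_length`` consecutive
edges between two distinct gene-list members.  Validity depends on the
run mode:

* ``downstream`` — every directed edge is traversed along its stored
  direction (undirected edges are free); the path follows the flow of
  the network, tracing activated pathways.
* ``upstream`` — the path first runs *against* edge direction from the
  start gene up to a common regulator (the apex), then forward down to
  the end gene; both terminal edges must be regulatory interaction
  types.  Both segments are nonempty, so the apex is a genuine shared
  regulator of the two genes.

For each ordered pair of list genes the ``k`` most probable valid paths
are retained; this bounded path set is the tractable approximation over
which connectivity probabilities are later computed.
"""
from __future__ import annotations

import dataclasses
import heapq
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .graphio import Edge, GeneList, InteractionNetwork
from .probnet import ProbabilisticNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "Path",
    "PathSet",
    "DEFAULT_REGULATORY_TYPES",
    "validate_config",
    "is_valid_path",
    "enumerate_valid_paths",
    "k_best_paths",
]

MODES = ("upstream", "downstream")
PATH_LENGTH_RANGE = (2, 5)
K_RANGE = (5, 50)
DEFAULT_PATH_LENGTH = 4
DEFAULT_K = 10
#: Interaction types accepted as regulatory terminal edges in upstream mode.
DEFAULT_REGULATORY_TYPES = frozenset({"pd", "srna"})


class ConfigError(ValueError):
    """Raised when a run configuration is outside the permitted ranges."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a single inference run.

    ``cost`` is the per-edge sparsity penalty of the objective;
    ``max_path_length`` counts edges (2-5, default 4); ``k`` (5-50,
    default 10) bounds retained paths per ordered gene pair, or per start
    gene when ``k_scope`` is ``"start"``.
    """

    mode: str
    cost: float
    max_path_length: Optional[int] = None
    k: Optional[int] = None
    regulatory_types: FrozenSet[str] = DEFAULT_REGULATORY_TYPES
    k_scope: str = "pair"


def validate_config(config: RunConfig) -> RunConfig:
    """Fill defaults and enforce the permitted parameter ranges."""
    if config.mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {config.mode!r}")
    if not (config.cost >= 0.0):
        raise ConfigError(f"cost must be a nonnegative real, got {config.cost!r}")
    length = config.max_path_length if config.max_path_length is not None else DEFAULT_PATH_LENGTH
    lo, hi = PATH_LENGTH_RANGE
    if not (isinstance(length, int) and lo <= length <= hi):
        raise ConfigError(f"max_path_length must be an integer in [{lo}, {hi}], got {length!r}")
    k = config.k if config.k is not None else DEFAULT_K
    klo, khi = K_RANGE
    if not (isinstance(k, int) and klo <= k <= khi):
        raise ConfigError(f"k must be an integer in [{klo}, {khi}], got {k!r}")
    reg = frozenset(config.regulatory_types)
    if config.mode == "upstream" and not reg:
        raise ConfigError("upstream mode requires a nonempty set of regulatory types")
    if config.k_scope not in ("pair", "start"):
        raise ConfigError(f"k_scope must be 'pair' or 'start', got {config.k_scope!r}")
    return dataclasses.replace(
        config, max_path_length=length, k=k, regulatory_types=reg
    )


@dataclass(frozen=True)
class Path:
    """An acyclic traversal with its probability.

    ``orientations[i]`` is True when ``edges[i]`` is traversed from its
    stored source to its stored target.  ``split_index`` (upstream mode)
    is the number of edges in the against-direction prefix; None in
    downstream mode.
    """

    nodes: Tuple[str, ...]
    edges: Tuple[Edge, ...]
    orientations: Tuple[bool, ...]
    probability: float
    split_index: Optional[int] = None

    @property
    def start(self) -> str:
        return self.nodes[0]

    @property
    def end(self) -> str:
        return self.nodes[-1]

    @property
    def length(self) -> int:
        return len(self.edges)

    def edge_set(self) -> FrozenSet[Edge]:
        return frozenset(self.edges)


def _sort_key(path: Path):
    # Descending probability, ties broken lexicographically on the node
    # sequence then the edge identity triples, so output is reproducible.
    return (
        -path.probability,
        path.nodes,
        tuple(e.key for e in path.edges),
    )


@dataclass
class PathSet:
    """Retained k-best paths, indexed by start gene and by ordered pair."""

    network: ProbabilisticNetwork
    by_pair: Dict[Tuple[str, str], List[Path]] = field(default_factory=dict)
    config: Optional[RunConfig] = None

    @property
    def by_start(self) -> Dict[str, List[Path]]:
        pooled: Dict[str, List[Path]] = defaultdict(list)
        for (a, _y), paths in self.by_pair.items():
            pooled[a].extend(paths)
        return {a: sorted(ps, key=_sort_key) for a, ps in pooled.items()}

    @property
    def starts(self) -> List[str]:
        return sorted({a for a, _ in self.by_pair})

    def all_edges(self) -> Set[Edge]:
        """Union of edges over all retained paths (the optimizer universe)."""
        return {e for paths in self.by_pair.values() for p in paths for e in p.edges}

    def n_paths(self) -> int:
        return sum(len(ps) for ps in self.by_pair.values())


def _step_forward_ok(edge: Edge, forward: bool) -> bool:
    # Downstream steps and upstream suffix steps follow the network flow.
    return forward or not edge.directed


def _step_against_ok(edge: Edge, forward: bool) -> bool:
    # Upstream prefix steps run against the flow; undirected edges are free.
    return (not forward) or not edge.directed


def is_valid_path(path: Path, config: RunConfig) -> bool:
    """Pure predicate: does the traversal satisfy the run-mode rules?

    Also checks the structural invariants (acyclic, 2 to
    ``max_path_length`` edges, consecutive edges share nodes).
    """
    cfg = validate_config(config)
    n = path.length
    if not (2 <= n <= cfg.max_path_length):
        return False
    if len(path.nodes) != n + 1 or len(path.orientations) != n:
        return False
    if len(set(path.nodes)) != len(path.nodes):
        return False
    for i, (e, fwd) in enumerate(zip(path.edges, path.orientations)):
        frm, to = (e.source, e.target) if fwd else (e.target, e.source)
        if path.nodes[i] != frm or path.nodes[i + 1] != to:
            return False
    if cfg.mode == "downstream":
        return all(_step_forward_ok(e, f) for e, f in zip(path.edges, path.orientations))
    # Upstream: both terminal edges regulatory, and some split m in
    # [1, n-1] with prefix edges against-or-undirected and suffix edges
    # forward-or-undirected.
    if path.edges[0].interaction_type not in cfg.regulatory_types:
        return False
    if path.edges[-1].interaction_type not in cfg.regulatory_types:
        return False
    prefix_ok = [_step_against_ok(e, f) for e, f in zip(path.edges, path.orientations)]
    suffix_ok = [_step_forward_ok(e, f) for e, f in zip(path.edges, path.orientations)]
    for m in range(1, n):
        if all(prefix_ok[:m]) and all(suffix_ok[m:]):
            return True
    return False


def _adjacency(network: InteractionNetwork) -> Dict[str, List[Tuple[Edge, bool, str]]]:
    """Per-node incident edges with both traversal orientations."""
    adj: Dict[str, List[Tuple[Edge, bool, str]]] = defaultdict(list)
    for e in network.edges:
        adj[e.source].append((e, True, e.target))
        adj[e.target].append((e, False, e.source))
    for v in adj:
        adj[v].sort(key=lambda t: (t[0], not t[1]))
    return dict(adj)


def _iter_valid_paths(
    pnet: ProbabilisticNetwork,
    start: str,
    targets: Set[str],
    config: RunConfig,
    adj: Optional[Dict[str, List[Tuple[Edge, bool, str]]]] = None,
) -> Iterator[Path]:
    """Depth-first generation of all mode-valid paths from ``start``.

    Upstream paths are explored with an explicit prefix/suffix phase; an
    undirected edge can serve in either phase, so the same edge sequence
    may be reachable under several splits — duplicates are suppressed and
    the smallest split index is kept.
    """
    cfg = validate_config(config)
    net = pnet.network
    if start not in net.nodes:
        raise ValueError(f"start gene {start!r} not in network")
    if adj is None:
        adj = _adjacency(net)
    targets = targets - {start}
    probs = pnet.edge_probability
    max_len = cfg.max_path_length
    upstream = cfg.mode == "upstream"
    reg = cfg.regulatory_types

    nodes: List[str] = [start]
    edges: List[Edge] = []
    orients: List[bool] = []
    on_path: Set[str] = {start}
    emitted: Set[Tuple[Tuple[str, ...], Tuple[Tuple[str, str, str], ...]]] = set()

    def emit(prob: float, split: Optional[int]) -> Iterator[Path]:
        key = (tuple(nodes), tuple(e.key for e in edges))
        if key in emitted:
            return
        emitted.add(key)
        yield Path(
            nodes=tuple(nodes),
            edges=tuple(edges),
            orientations=tuple(orients),
            probability=prob,
            split_index=split,
        )

    def dfs(node: str, prob: float, phase: int, split: int) -> Iterator[Path]:
        depth = len(edges)
        if depth >= 2 and node in targets:
            if not upstream:
                yield from emit(prob, None)
            elif phase == 1 and edges[-1].interaction_type in reg:
                yield from emit(prob, split)
        if depth == max_len:
            return
        for e, fwd, nxt in adj.get(node, ()):
            if nxt in on_path:
                continue
            if upstream and depth == 0 and e.interaction_type not in reg:
                continue
            steps: List[Tuple[int, int]] = []  # (new_phase, new_split)
            if upstream:
                # Switching to the suffix before extending the prefix makes
                # the first emission of an edge sequence carry its smallest
                # feasible split index.
                if phase == 0 and depth >= 1 and _step_forward_ok(e, fwd):
                    steps.append((1, depth))
                if phase == 0 and _step_against_ok(e, fwd):
                    steps.append((0, split))
                if phase == 1 and _step_forward_ok(e, fwd):
                    steps.append((1, split))
            else:
                if _step_forward_ok(e, fwd):
                    steps.append((1, 0))
            if not steps:
                continue
            nodes.append(nxt)
            edges.append(e)
            orients.append(fwd)
            on_path.add(nxt)
            for new_phase, new_split in steps:
                yield from dfs(nxt, prob * probs[e], new_phase, new_split)
            on_path.discard(nxt)
            nodes.pop()
            edges.pop()
            orients.pop()

    yield from dfs(start, 1.0, 0 if upstream else 1, 0)


def enumerate_valid_paths(
    pnet: ProbabilisticNetwork,
    start: str,
    targets: Iterable[str],
    config: RunConfig,
) -> List[Path]:
    """Exhaustively enumerate mode-valid acyclic paths from ``start``.

    Brute-force reference for the k-best search; intended for small
    graphs and testing.  Output is sorted by descending probability with
    deterministic tie-breaking.
    """
    paths = list(_iter_valid_paths(pnet, start, set(targets), config))
    paths.sort(key=_sort_key)
    return paths


def k_best_paths(
    pnet: ProbabilisticNetwork, gene_list: GeneList, config: RunConfig
) -> PathSet:
    """Retain the k most probable valid paths per ordered gene pair.

    List genes absent from the network are dropped with a warning.  With
    ``k_scope="start"`` the k bound instead pools all end genes of a
    start gene.  Paths with probability 0 are legal and retained when
    nothing better exists.
    """
    cfg = validate_config(config)
    net = pnet.network
    effective = [g for g in gene_list if g in net.nodes]
    dropped = [g for g in gene_list if g not in net.nodes]
    if dropped:
        logger.warning(
            "%d gene-list member(s) absent from the network dropped: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not effective:
        raise ValueError("no list genes in network")
    adj = _adjacency(net)
    listed = set(effective)
    by_pair: Dict[Tuple[str, str], List[Path]] = {}
    for a in effective:
        # Bounded DFS enumerates all valid paths (length <= 5 keeps this
        # tractable); a heap per pair keeps the k best seen.
        heaps: Dict[str, List] = defaultdict(list)
        counter = 0
        for path in _iter_valid_paths(pnet, a, listed, cfg, adj=adj):
            counter += 1
            key = _sort_key(path)
            group = a if cfg.k_scope == "start" else path.end
            # heapq is a min-heap; _HeapKey inverts comparison so the
            # worst retained path sits at the root.
            heap = heaps[group]
            item = (_HeapKey(key), counter, path)
            if len(heap) < cfg.k:
                heapq.heappush(heap, item)
            elif key < heap[0][0].key:
                # The inverted-comparison root is the worst retained path;
                # replace it when the new path sorts strictly better.
                heapq.heappushpop(heap, item)
        for group, heap in heaps.items():
            retained = sorted((item[2] for item in heap), key=_sort_key)
            if cfg.k_scope == "start":
                for path in retained:
                    by_pair.setdefault((a, path.end), []).append(path)
            else:
                by_pair[(a, group)] = retained
    if cfg.k_scope == "start":
        for pair in by_pair:
            by_pair[pair].sort(key=_sort_key)
    return PathSet(network=pnet, by_pair=by_pair, config=cfg)


class _HeapKey:
    """Inverts path sort-key comparison so heapq keeps the best k paths."""

    __slots__ = ("key",)

    def __init__(self, key):
        self.key = key

    def __lt__(self, other: "_HeapKey") -> bool:
        return self.key > other.key

    def __eq__(self, other) -> bool:  # pragma: no cover - heap bookkeeping
        return self.key == other.key
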