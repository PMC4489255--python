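"""Shared fixtures and small graph-building helpers."""
from __future__ import annotations

import numpy as np
import pytest

from subnetx.graphio import Edge, InteractionNetwork
from subnetx.pathfinder import Path
from subnetx.probnet import ProbabilisticNetwork


def make_pnet(edge_specs, probs=None) -> ProbabilisticNetwork:
    """Build a probabilistic network from (src, tgt, type, directed) specs.

    ``probs`` maps spec index -> probability; unspecified edges get 1.0.
    """
    edges = [Edge(*spec) for spec in edge_specs]
    net = InteractionNetwork.from_edges(edges)
    probs = probs or {}
    edge_probs = {e: float(probs.get(i, 1.0)) for i, e in enumerate(edges)}
    scores = {n: 0.5 for n in net.nodes}
    return ProbabilisticNetwork(network=net, edge_probability=edge_probs, node_score=scores)


def make_path(pnet: ProbabilisticNetwork, node_seq, edge_indices, orientations=None):
    """Assemble a Path over the pnet's edge list by index."""
    edges = tuple(pnet.network.edges[i] for i in edge_indices)
    if orientations is None:
        orientations = tuple(
            e.source == node_seq[i] for i, e in enumerate(edges)
        )
    prob = 1.0
    for e in edges:
        prob *= pnet.edge_probability[e]
    return Path(
        nodes=tuple(node_seq),
        edges=edges,
        orientations=tuple(orientations),
        probability=prob,
    )


def random_pnet(rng: np.random.Generator, n_nodes: int, n_edges: int) -> ProbabilisticNetwork:
    """Random typed mixed graph with uniform edge probabilities."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    types = [("pd", True), ("pp", False), ("met", True)]
    edges = []
    seen = set()
    attempts = 0
    while len(edges) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        etype, directed = types[rng.integers(0, len(types))]
        key = (nodes[i], nodes[j], etype)
        if key in seen:
            continue
        seen.add(key)
        edges.append(Edge(nodes[i], nodes[j], etype, directed))
    if not edges:
        edges = [Edge(nodes[0], nodes[1], "pd", True)]
    net = InteractionNetwork.from_edges(edges, extra_nodes=nodes)
    probs = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    scores = {n: 0.5 for n in net.nodes}
    return ProbabilisticNetwork(network=net, edge_probability=probs, node_score=scores)


@pytest.fixture
def toy_pnet() -> ProbabilisticNetwork:
    """A -pd-> B, B --pp-- C, C -met-> D with unit probabilities."""
    return make_pnet(
        [
            ("A", "B", "pd", True),
            ("B", "C", "pp", False),
            ("C", "D", "met", True),
        ]
    )


@pytest.fixture
def apex_pnet() -> ProbabilisticNetwork:
    """Regulator apex: R -pd-> A, R -pd-> Y plus a pp bridge A--Y."""
    return make_pnet(
        [
            ("R", "A", "pd", True),
            ("R", "Y", "pd", True),
            ("A", "Y", "pp", False),
        ],
        probs={0: 0.9, 1: 0.8, 2: 0.5},
    )
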