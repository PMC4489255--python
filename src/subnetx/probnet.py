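"""Conversion of an interaction network into a probabilistic network.

The differential-expression evidence for each gene is turned into a node
score in [0, 1]: assuming log fold changes follow a normal distribution
``N(mu, sigma)`` fitted to the whole expression table, the score of a gene
with log fold change ``D`` is

    Score_gene = | 1 - 2 * Phi_(mu, sigma)(D) |

which is 0 for a gene at the centre of the distribution and approaches 1
for extreme over- or under-expression (it equals one minus the two-tailed
normal p-value of ``D``).  The presence probability of an edge is the
product of the scores of its two endpoints, so edges between strongly
differentially expressed genes are likely "on" in the probed condition.
Genes without a measurement score 0.5, a neutral prior.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.stats import norm

from .graphio import Edge, ExpressionTable, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStats",
    "ProbabilisticNetwork",
    "UNMEASURED_SCORE",
    "fit_expression_stats",
    "gene_score",
    "edge_probability",
    "build_probabilistic_network",
]

#: Neutral score assigned to genes absent from the expression table.
UNMEASURED_SCORE = 0.5


@dataclass(frozen=True)
class ExpressionStats:
    """Normal fit ``N(mu, sigma)`` to the observed log fold changes."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.sigma)):
            raise ValueError("expression statistics must be finite")
        if self.sigma <= 0:
            raise ValueError("degenerate expression distribution: sigma must be > 0")


@dataclass
class ProbabilisticNetwork:
    """An interaction network with a presence probability per edge.

    ``node_score`` covers every network node (unmeasured genes at 0.5);
    ``edge_probability`` covers every edge and lies in [0, 1].
    """

    network: InteractionNetwork
    edge_probability: Dict[Edge, float]
    node_score: Dict[str, float] = field(default_factory=dict)
    stats: ExpressionStats | None = None

    def __post_init__(self) -> None:
        for e in self.network.edges:
            if e not in self.edge_probability:
                raise ValueError(f"edge {e} has no probability")
            p = self.edge_probability[e]
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge probability {p} out of [0, 1] for {e}")
        for g, s in self.node_score.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"node score {s} out of [0, 1] for {g}")


def fit_expression_stats(table: ExpressionTable) -> ExpressionStats:
    """Fit mean and sample (n-1) standard deviation of the log fold changes.

    Fails on fewer than two genes or on a zero-variance table, where the
    normal model is meaningless.
    """
    values = np.asarray(list(table.values()), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 expression values to fit statistics")
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate expression distribution: sigma must be > 0")
    return ExpressionStats(mu=mu, sigma=sigma)


def gene_score(d: float, stats: ExpressionStats) -> float:
    """Node score ``|1 - 2 * Phi_(mu, sigma)(d)|`` for log fold change ``d``.

    Symmetric about ``mu`` and strictly increasing in ``|d - mu|``; equals
    ``2 * Phi(|z|) - 1`` of the z-transformed value, i.e. one minus the
    two-tailed normal p-value.
    """
    if not math.isfinite(d):
        raise ValueError(f"log fold change must be finite, got {d!r}")
    phi = norm.cdf(d, loc=stats.mu, scale=stats.sigma)
    return abs(1.0 - 2.0 * float(phi))


def edge_probability(score_a: float, score_b: float) -> float:
    """Presence probability of an edge: the product of its endpoint scores."""
    for s in (score_a, score_b):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s!r} out of [0, 1]")
    return score_a * score_b


def build_probabilistic_network(
    network: InteractionNetwork, table: ExpressionTable
) -> ProbabilisticNetwork:
    """Assign every edge the product of its endpoint gene scores.

    The normal model is fitted on all genes in the expression table (not
    only on network genes).  Network genes missing from the table receive
    the neutral score 0.5; their count is logged.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    stats = fit_expression_stats(table)
    scores: Dict[str, float] = {}
    n_missing = 0
    for gene in sorted(network.nodes):
        if gene in table:
            scores[gene] = gene_score(table[gene], stats)
        else:
            scores[gene] = UNMEASURED_SCORE
            n_missing += 1
    if n_missing:
        logger.info(
            "%d of %d network genes have no expression measurement (score 0.5)",
            n_missing,
            network.n_nodes,
        )
    probs = {
        e: edge_probability(scores[e.source], scores[e.target]) for e in network.edges
    }
    return ProbabilisticNetwork(
        network=network, edge_probability=probs, node_score=scores, stats=stats
    )
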