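"""Readers and writers for the external file formats.

Interaction networks are 4-column TSV (source, target, type, directed
flag), expression tables are 2-column TSV (gene, log fold change), gene
lists are one identifier per line.  Results are exported as Cytoscape
SIF and as a round-trippable JSON document.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "InteractionNetwork",
    "ExpressionTable",
    "GeneList",
    "ParseError",
    "read_network",
    "write_network",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "read_sif",
    "write_sif",
    "write_result_json",
    "read_result_json",
]

#: Mapping from gene identifier to log2 fold change.
ExpressionTable = Dict[str, float]

#: Ordered, de-duplicated list of gene identifiers.
GeneList = List[str]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class Edge:
    """A typed interaction between two distinct biological entities.

    ``directed`` marks whether the stored ``source -> target`` orientation
    is meaningful (protein-DNA, sRNA, directed metabolic steps) or merely
    notational (protein-protein contacts).
    """

    source: str
    target: str
    interaction_type: str
    directed: bool

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop edge on {self.source!r} is not allowed")
        if not self.interaction_type:
            raise ValueError("interaction_type must be nonempty")

    @property
    def key(self) -> Tuple[str, str, str]:
        """Identity triple: parallel edges of different type are distinct."""
        return (self.source, self.target, self.interaction_type)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        arrow = "->" if self.directed else "--"
        return f"{self.source} {arrow}[{self.interaction_type}] {self.target}"


@dataclass
class InteractionNetwork:
    """A mixed graph of typed, optionally directed interactions."""

    nodes: Set[str] = field(default_factory=set)
    edges: List[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: Set[Tuple[str, str, str]] = set()
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e} references a node outside the network")
            if e.key in seen:
                raise ValueError(f"duplicate edge triple {e.key}")
            seen.add(e.key)

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        edges = list(edges)
        nodes: Set[str] = set(extra_nodes)
        for e in edges:
            nodes.add(e.source)
            nodes.add(e.target)
        return cls(nodes=nodes, edges=edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def read_network(path) -> InteractionNetwork:
    """Load a 4-column TSV interaction network.

    Lines starting with ``#`` and blank lines are skipped.  Self-loops are
    rejected with a warning; duplicate (source, target, type) triples are
    collapsed to the first occurrence with a warning.
    """
    edges: List[Edge] = []
    seen: Set[Tuple[str, str, str]] = set()
    n_dup = n_self = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields "
                    f"(source, target, type, directed), got {len(parts)}"
                )
            source, target, etype, dflag = (p.strip() for p in parts)
            if dflag not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: directed flag must be 0 or 1, got {dflag!r}"
                )
            if not etype:
                raise ParseError(f"{path}:{lineno}: empty interaction type")
            if source == target:
                n_self += 1
                logger.warning("%s:%d: self-loop on %r skipped", path, lineno, source)
                continue
            key = (source, target, etype)
            if key in seen:
                n_dup += 1
                logger.warning("%s:%d: duplicate edge %s collapsed", path, lineno, key)
                continue
            seen.add(key)
            edges.append(Edge(source, target, etype, dflag == "1"))
    if not edges:
        raise ParseError(f"{path}: no edges")
    if n_dup or n_self:
        logger.info(
            "%s: dropped %d duplicate and %d self-loop line(s)", path, n_dup, n_self
        )
    return InteractionNetwork.from_edges(edges)


def write_network(network: InteractionNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in network.edges:
            fh.write(
                f"{e.source}\t{e.target}\t{e.interaction_type}\t{int(e.directed)}\n"
            )


def read_expression(path) -> ExpressionTable:
    """Load a 2-column TSV of gene -> log fold change.

    An optional single header line is tolerated; later duplicates of a gene
    overwrite earlier entries with a warning.
    """
    table: ExpressionTable = {}
    first_data_line = True
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            gene, value_str = parts[0].strip(), parts[1].strip()
            try:
                value = float(value_str)
            except ValueError:
                if first_data_line:
                    first_data_line = False  # header line
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-numeric log fold change {value_str!r}"
                ) from None
            if value != value or value in (float("inf"), float("-inf")):
                raise ParseError(f"{path}:{lineno}: non-finite log fold change")
            first_data_line = False
            if gene in table:
                logger.warning(
                    "%s:%d: duplicate gene %r, keeping later value", path, lineno, gene
                )
            table[gene] = value
    return table


def write_expression(table: Mapping[str, float], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, value in table.items():
            fh.write(f"{gene}\t{value:.6f}\n")


def read_gene_list(path) -> GeneList:
    """Load a one-identifier-per-line gene list, order-preserving, de-duplicated."""
    genes: GeneList = []
    seen: Set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            gene = raw.strip()
            if not gene or gene.startswith("#"):
                continue
            if gene in seen:
                continue
            seen.add(gene)
            genes.append(gene)
    if not genes:
        raise ParseError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(gene + "\n")


def write_sif(subnetwork, path) -> None:
    """Write a sub-network in Cytoscape SIF format, one edge per line.

    Lines are ``source<TAB>type<TAB>target`` in lexicographic order so
    identical sub-networks always serialize identically.
    """
    lines = sorted(
        f"{e.source}\t{e.interaction_type}\t{e.target}" for e in subnetwork.edges
    )
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_sif(path) -> List[Tuple[str, str, str]]:
    """Read SIF lines back as (source, type, target) triples."""
    triples: List[Tuple[str, str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 SIF fields")
            triples.append((parts[0], parts[1], parts[2]))
    return triples


def write_result_json(
    subnetwork,
    node_scores: Mapping[str, float],
    edge_probabilities: Mapping[Edge, float],
    path,
    log_fold_changes: Mapping[str, float] | None = None,
) -> None:
    """Serialize a sub-network with node scores and edge probabilities.

    Every sub-network node must have a score; genes absent from the
    expression table get ``null`` log fold change.
    """
    log_fold_changes = log_fold_changes or {}
    nodes = sorted(subnetwork.nodes)
    missing = [n for n in nodes if n not in node_scores]
    if missing:
        raise ValueError(f"missing node score(s) for: {', '.join(sorted(missing))}")
    doc = {
        "nodes": [
            {
                "id": n,
                "score": node_scores[n],
                "log_fold_change": log_fold_changes.get(n),
            }
            for n in nodes
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "type": e.interaction_type,
                "directed": e.directed,
                "probability": edge_probabilities[e],
            }
            for e in sorted(subnetwork.edges)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_result_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
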