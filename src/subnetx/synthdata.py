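"""Self-contained synthetic scenarios with planted regulatory structure.

A scenario is a typed mixed graph plus a matching expression experiment:
a handful of planted regulator hubs each control a block of target genes
through directed protein-DNA edges; targets receive large log fold
changes of a per-regulator sign, background genes draw from a centred
normal.  Protein-protein (undirected) and metabolic (directed) edges
form an Erdős–Rényi-style background.  The gene list is derived from
the expression table by an absolute log-fold-change cutoff (default
1.5), mirroring how differential-expression gene lists are built in
practice.  A small GAF file annotates each regulator module so the
enrichment step is exercised end to end.

Everything is driven by one seed and writes byte-identical bundles on
repeated runs.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np

from .graphio import (
    Edge,
    InteractionNetwork,
    write_expression,
    write_gene_list,
    write_network,
)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "ScenarioBundle", "generate_scenario"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs of the generator; defaults define the standard study scenario.

    Edge counts are background edges per type; planted regulator->target
    protein-DNA edges come on top.  ``effect_size`` is the mean absolute
    log fold change of targets, ``noise`` the standard deviation of all
    log fold changes, ``lfc_cutoff`` the gene-list selection threshold.
    """

    n_genes: int = 200
    n_pd: int = 120
    n_pp: int = 160
    n_met: int = 80
    n_regulators: int = 2
    targets_per_regulator: int = 20
    effect_size: float = 3.0
    noise: float = 1.0
    lfc_cutoff: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_pd": self.n_pd,
            "n_pp": self.n_pp,
            "n_met": self.n_met,
            "n_regulators": self.n_regulators,
            "targets_per_regulator": self.targets_per_regulator,
        }
        for name, value in counts.items():
            if not (isinstance(value, int) and value > 0):
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if not self.effect_size > 0:
            raise ValueError("effect_size must be > 0")
        if not self.noise > 0:
            raise ValueError("noise must be > 0")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be >= 0")
        needed = self.n_regulators * (1 + self.targets_per_regulator)
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible spec: {needed} regulator/target genes > {self.n_genes} genes"
            )
        if self.n_pd + self.n_regulators * self.targets_per_regulator > self.n_genes * (
            self.n_genes - 1
        ):
            raise ValueError("infeasible spec: more pd edges than ordered pairs")


@dataclass
class ScenarioBundle:
    """Generated files plus the planted ground truth (in memory only)."""

    spec: ScenarioSpec
    network_path: str
    expression_path: str
    gene_list_path: str
    gaf_path: str
    regulators: List[str] = field(default_factory=list)
    targets: Dict[str, List[str]] = field(default_factory=dict)
    gene_list: List[str] = field(default_factory=list)
    expression: Dict[str, float] = field(default_factory=dict)

    @property
    def all_targets(self) -> Set[str]:
        return {t for ts in self.targets.values() for t in ts}


def _gene_names(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_scenario(spec: ScenarioSpec, out_dir) -> ScenarioBundle:
    """Write network TSV, expression TSV, gene list and GAF into ``out_dir``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    genes = _gene_names(spec.n_genes)

    # Planted structure: regulators and disjoint target blocks.
    special = rng.choice(
        spec.n_genes,
        size=spec.n_regulators * (1 + spec.targets_per_regulator),
        replace=False,
    )
    regulators = [genes[i] for i in special[: spec.n_regulators]]
    targets: Dict[str, List[str]] = {}
    cursor = spec.n_regulators
    for r in regulators:
        block = special[cursor : cursor + spec.targets_per_regulator]
        targets[r] = sorted(genes[i] for i in block)
        cursor += spec.targets_per_regulator

    edges: List[Edge] = []
    seen: Set[Tuple[str, str, str]] = set()

    def add(src: str, tgt: str, etype: str, directed: bool) -> bool:
        if src == tgt:
            return False
        key = (src, tgt, etype)
        if key in seen:
            return False
        seen.add(key)
        edges.append(Edge(src, tgt, etype, directed))
        return True

    for r in regulators:
        for t in targets[r]:
            add(r, t, "pd", True)

    def add_random_directed(etype: str, count: int) -> None:
        added = 0
        while added < count:
            i, j = rng.integers(0, spec.n_genes, size=2)
            if i == j:
                continue
            if add(genes[i], genes[j], etype, True):
                added += 1

    add_random_directed("pd", spec.n_pd)
    # Undirected protein-protein background via a G(n, m) random graph.
    pp_seed = int(rng.integers(0, 2**31 - 1))
    max_pp = spec.n_genes * (spec.n_genes - 1) // 2
    g_pp = nx.gnm_random_graph(spec.n_genes, min(spec.n_pp, max_pp), seed=pp_seed)
    for i, j in sorted(g_pp.edges()):
        add(genes[i], genes[j], "pp", False)
    add_random_directed("met", spec.n_met)

    network = InteractionNetwork.from_edges(edges, extra_nodes=genes)

    # Expression: per-regulator effect sign, centred background.
    signs = {r: (1.0 if rng.random() < 0.5 else -1.0) for r in regulators}
    expression: Dict[str, float] = {}
    target_of: Dict[str, str] = {
        t: r for r, ts in targets.items() for t in ts
    }
    for gene in genes:
        if gene in target_of:
            r = target_of[gene]
            lfc = rng.normal(signs[r] * spec.effect_size, spec.noise)
        else:
            lfc = rng.normal(0.0, spec.noise)
        expression[gene] = float(lfc)

    gene_list = [g for g in genes if abs(expression[g]) > spec.lfc_cutoff]
    if not gene_list:
        raise ValueError("scenario produced an empty gene list; raise effect_size")

    network_path = os.path.join(out_dir, "network.tsv")
    expression_path = os.path.join(out_dir, "expression.tsv")
    gene_list_path = os.path.join(out_dir, "genelist.txt")
    gaf_path = os.path.join(out_dir, "annotations.gaf")
    write_network(network, network_path)
    write_expression(expression, expression_path)
    write_gene_list(gene_list, gene_list_path)
    _write_gaf(gaf_path, regulators, targets, genes, rng)

    logger.info(
        "scenario seed=%d: %d genes, %d edges, %d list genes (%d planted targets)",
        spec.seed,
        spec.n_genes,
        network.n_edges,
        len(gene_list),
        sum(1 for g in gene_list if g in target_of),
    )
    return ScenarioBundle(
        spec=spec,
        network_path=network_path,
        expression_path=expression_path,
        gene_list_path=gene_list_path,
        gaf_path=gaf_path,
        regulators=regulators,
        targets=targets,
        gene_list=gene_list,
        expression=expression,
    )


def _write_gaf(
    path,
    regulators: List[str],
    targets: Dict[str, List[str]],
    genes: List[str],
    rng: np.random.Generator,
) -> None:
    """Synthetic GAF 2.2 file: one term per regulator module + one broad term."""

    def row(gene: str, term: str) -> str:
        fields = [
            "SYN",  # DB
            gene,  # DB object id
            gene,  # DB object symbol
            "",  # qualifier
            term,  # GO id
            "SYN_REF:0000001",
            "IEA",
            "",
            "P",
            "",
            "",
            "gene",
            "taxon:32644",
            "20240101",
            "SYN",
            "",
            "",
        ]
        return "\t".join(fields)

    lines = ["!gaf-version: 2.2"]
    for idx, r in enumerate(regulators, start=1):
        term = f"GO:{idx:07d}"
        for gene in sorted([r, *targets[r]]):
            lines.append(row(gene, term))
    broad_term = f"GO:{len(regulators) + 1:07d}"
    broad = rng.choice(len(genes), size=max(2, len(genes) // 10), replace=False)
    for i in sorted(broad):
        lines.append(row(genes[i], broad_term))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
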