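"""Hypergeometric term enrichment of sub-network genes.

Annotations come from a GAF 2.x file; the enrichment universe is the
set of genes in the loaded interaction network (the frame the
sub-network was drawn from).  Per term with at least one sub-network
gene, the upper-tail hypergeometric p-value P(X >= k | N, K, n) is
reported together with a Benjamini-Hochberg q-value.  Annotations are
used exactly as given — no GO-graph propagation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graphio import ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationMap",
    "EnrichmentRow",
    "read_gaf",
    "enrich",
    "write_enrichment_tsv",
]


@dataclass
class AnnotationMap:
    """Term -> annotated gene set, with optional display names."""

    terms: Dict[str, Set[str]] = field(default_factory=dict)
    names: Dict[str, str] = field(default_factory=dict)

    def name(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    name: str
    k: int  # annotated genes in the sub-network
    K: int  # annotated genes in the background
    n: int  # sub-network size
    N: int  # background size
    p_value: float
    q_value: float


def read_gaf(path) -> AnnotationMap:
    """Parse a GAF 2.x association file.

    Gene symbols come from column 3, GO identifiers from column 5; rows
    whose qualifier contains NOT are skipped, as are '!' comment lines.
    GAF carries no term names, so terms display as their identifiers.
    """
    terms: Dict[str, Set[str]] = {}
    n_rows = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 15:
                raise ParseError(
                    f"{path}:{lineno}: GAF line has {len(parts)} columns, expected >= 15"
                )
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                continue
            gene = parts[2].strip()
            term = parts[4].strip()
            if not gene or not term:
                raise ParseError(f"{path}:{lineno}: empty gene symbol or GO id")
            terms.setdefault(term, set()).add(gene)
            n_rows += 1
    if not terms:
        logger.warning("%s: no usable annotation rows", path)
    return AnnotationMap(terms=terms)


def enrich(
    subnetwork_genes: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationMap,
) -> List[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment over the background universe.

    Only terms with at least one sub-network gene are tested; rows are
    sorted by ascending p-value with q-values computed over all tested
    terms (Benjamini-Hochberg step-up).
    """
    background = set(background)
    sub = set(subnetwork_genes)
    if not background:
        raise ValueError("empty background gene set")
    if not sub <= background:
        extra = sorted(sub - background)[:5]
        raise ValueError(f"sub-network genes outside background: {extra}")
    N = len(background)
    n = len(sub)
    tested: List[tuple] = []
    for term in sorted(annotations.terms):
        annotated = annotations.terms[term] & background
        K = len(annotated)
        k = len(annotated & sub)
        if k == 0:
            continue
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((term, k, K, p))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(
            term=term,
            name=annotations.name(term),
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
        )
        for (term, k, K, p), q in zip(tested, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def write_enrichment_tsv(rows: List[EnrichmentRow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tname\tk\tK\tn\tN\tp_value\tq_value\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
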