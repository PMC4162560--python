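"""DEG calling, mapping onto enzyme nodes, and sub-network induction.

A gene is differentially expressed (a DEG) when, in at least one contrast, it
passes fold change >= fc_min AND FDR <= fdr_max — both boundaries inclusive,
default fold change 2 and FDR 1e-10. The DEG-encoded enzymes induce a
sub-interaction network of the GECN; enzymes left without any incident edge
are dropped, which is why the mapped-enzyme count exceeds the sub-network
node count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .build import GECN
from .pgdb_io import PathwayDB, PPIEdgeList

logger = logging.getLogger(__name__)

__all__ = ["DEGSet", "SubNetwork", "call_degs", "map_degs_to_enzymes",
           "induce_subnetwork", "ppi_deg_neighbors"]


@dataclass
class DEGSet:
    """Genes passing the DE thresholds in at least one contrast.

    ``evidence`` maps gene id -> list of qualifying (contrast, log2fc, fdr)
    rows, preserving table order.
    """

    evidence: dict[str, list[tuple[str, float, float]]] = field(default_factory=dict)
    fc_min: float = 2.0
    fdr_max: float = 1e-10

    @property
    def genes(self) -> set[str]:
        return set(self.evidence)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.evidence

    def __len__(self) -> int:
        return len(self.evidence)


def call_degs(table: pd.DataFrame, fc_min: float = 2.0, fdr_max: float = 1e-10) -> DEGSet:
    """Filter a DEG table (gene_id, contrast, log2fc, fdr) to the DEG set.

    ``fc_min`` is a linear fold change (>= 1); a row qualifies when
    |log2fc| >= log2(fc_min) and fdr <= fdr_max, both inclusive. Rows with
    missing statistics are skipped with a warning.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (linear fold change)")
    if not (0 < fdr_max <= 1):
        raise ValueError("fdr_max must be in (0, 1]")
    lfc_min = math.log2(fc_min)
    out = DEGSet(fc_min=fc_min, fdr_max=fdr_max)
    n_bad = 0
    for row in table.itertuples(index=False):
        lfc, fdr = row.log2fc, row.fdr
        if lfc is None or fdr is None or (isinstance(lfc, float) and math.isnan(lfc)) \
                or (isinstance(fdr, float) and math.isnan(fdr)):
            n_bad += 1
            continue
        if abs(lfc) >= lfc_min and fdr <= fdr_max:
            out.evidence.setdefault(str(row.gene_id), []).append((str(row.contrast), float(lfc), float(fdr)))
    if n_bad:
        logger.warning("call_degs: %d row(s) with missing statistics skipped", n_bad)
    return out


def map_degs_to_enzymes(degs: DEGSet, db: PathwayDB) -> tuple[dict[str, tuple[str, ...]], dict[str, int]]:
    """Map DEGs onto enzymes through the gene-enzyme table.

    Returns ``(enzyme_id -> DEG gene ids, summary)`` where the summary counts
    distinct mapped genes (``n_genes_mapped``), enzymes with at least one DEG
    (``n_enzymes``) and DEGs encoding no enzyme (``n_genes_unmapped``).
    A gene encoding several enzymes appears once under each.
    """
    by_enzyme: dict[str, list[str]] = {}
    mapped_genes: set[str] = set()
    for gene, enzyme in db.gene_enzyme:
        if gene in degs:
            lst = by_enzyme.setdefault(enzyme, [])
            if gene not in lst:
                lst.append(gene)
            mapped_genes.add(gene)
    summary = {
        "n_genes_mapped": len(mapped_genes),
        "n_enzymes": len(by_enzyme),
        "n_genes_unmapped": len(degs.genes - mapped_genes),
    }
    return {e: tuple(gs) for e, gs in by_enzyme.items()}, summary


@dataclass
class SubNetwork:
    """GECN induced on DEG-encoded enzymes.

    ``network`` keeps the parent's directedness; ``deg_genes`` maps every
    retained node to its DEG gene ids. With isolated nodes dropped, every
    node has at least one incident edge.
    """

    network: GECN
    deg_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.network.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def n_edges(self) -> int:
        return self.network.n_edges


def induce_subnetwork(net: GECN, enzymes: dict[str, tuple[str, ...]] | set[str],
                      drop_isolated: bool = True) -> SubNetwork:
    """Induce the sub-network of ``net`` on ``enzymes``.

    ``enzymes`` may be a set of enzyme ids or the mapping returned by
    :func:`map_degs_to_enzymes` (node -> DEG genes). Ids absent from the
    network are ignored with a warning. Edges survive iff both endpoints are
    selected; when ``drop_isolated`` (default) nodes left with degree 0 are
    removed.
    """
    if isinstance(enzymes, dict):
        gene_map = {e: tuple(gs) for e, gs in enzymes.items()}
    else:
        gene_map = {e: () for e in enzymes}
    unknown = set(gene_map) - set(net.graph.nodes)
    if unknown:
        logger.warning("induce_subnetwork: %d id(s) not in the network ignored", len(unknown))
    keep = [n for n in net.graph.nodes if n in gene_map]
    sub = net.graph.subgraph(keep).copy()
    if drop_isolated:
        sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return SubNetwork(
        network=GECN(sub, directed=net.directed),
        deg_genes={n: gene_map[n] for n in sub.nodes},
    )


def ppi_deg_neighbors(protein: str, ppi: PPIEdgeList, degs: DEGSet) -> set[str]:
    """Interaction partners of ``protein`` that are DEGs."""
    return {g for g in ppi.neighbors(protein) if g in degs}
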