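"""Network topology statistics and cross-species overlap of enzyme networks.

Connected components and the NetworkAnalyzer-style connected-pairs count
describe a network's overall structure. Two organisms' networks are compared
by collapsing nodes onto EC numbers — the only species-independent key in
this data model — and intersecting the keyed node and edge sets.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .build import GECN, collapse_to_undirected

logger = logging.getLogger(__name__)

__all__ = ["ComponentDecomposition", "OverlapResult", "connected_components",
           "connected_pairs_count", "cross_species_overlap", "degree_stats"]


@dataclass
class ComponentDecomposition:
    """Connected components, largest first (ties: smallest member id), with
    per-component edge counts."""

    components: list[frozenset[str]] = field(default_factory=list)
    edge_counts: list[int] = field(default_factory=list)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def __len__(self) -> int:
        return len(self.components)


def _as_undirected(g: GECN | nx.Graph) -> nx.Graph:
    if isinstance(g, GECN):
        return collapse_to_undirected(g).graph if g.directed else g.graph
    return g.to_undirected() if g.is_directed() else g


def connected_components(g: GECN | nx.Graph) -> ComponentDecomposition:
    ug = _as_undirected(g)
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(ug)),
        key=lambda c: (-len(c), min(c)),
    )
    return ComponentDecomposition(
        components=comps,
        edge_counts=[ug.subgraph(c).number_of_edges() for c in comps],
    )


def connected_pairs_count(g: GECN | nx.Graph) -> int:
    """Number of unordered node pairs in the same component: sum of
    k*(k-1)/2 over component sizes k."""
    return sum(k * (k - 1) // 2 for k in connected_components(g).sizes)


def _ec_collapse(g: GECN) -> tuple[nx.Graph, int]:
    """Collapse a GECN onto EC-number keys.

    Nodes without an EC annotation are excluded (their count is returned);
    partial ECs such as ``2.4.1.-`` participate as plain strings. An edge
    joins two ECs iff any pair of their member enzymes is adjacent.
    """
    ug = _as_undirected(g)
    keyed = nx.Graph()
    skipped = 0
    ec_of: dict[str, str] = {}
    for node, data in ug.nodes(data=True):
        ec = (data.get("ec") or "").strip()
        if not ec:
            skipped += 1
            continue
        ec_of[node] = ec
        keyed.add_node(ec)
    for u, v in ug.edges:
        eu, ev = ec_of.get(u), ec_of.get(v)
        if eu and ev and eu != ev:
            keyed.add_edge(eu, ev)
    return keyed, skipped


@dataclass
class OverlapResult:
    """EC-keyed intersection of two networks."""

    shared_ecs: frozenset[str]
    graph: nx.Graph
    components: ComponentDecomposition
    #: per-input counts of nodes excluded for lacking an EC key
    unkeyed_nodes: tuple[int, int] = (0, 0)

    @property
    def n_shared(self) -> int:
        return len(self.shared_ecs)


def _ec_covers(partial: str, full: str) -> bool:
    pp, fp = partial.split("."), full.split(".")
    return len(pp) == len(fp) == 4 and all(a == b or a == "-" for a, b in zip(pp, fp))


def _expand_partials(keyed: nx.Graph, universe: set[str]) -> nx.Graph:
    """Rewrite each partial-EC node to every full EC in ``universe`` it
    covers (keeping the partial itself when nothing matches)."""
    out = nx.Graph()
    targets = {
        ec: sorted(f for f in universe if _ec_covers(ec, f)) or [ec]
        if "-" in ec else [ec]
        for ec in keyed.nodes
    }
    for ec in keyed.nodes:
        out.add_nodes_from(targets[ec])
    for u, v in keyed.edges:
        for tu in targets[u]:
            for tv in targets[v]:
                if tu != tv:
                    out.add_edge(tu, tv)
    return out


def cross_species_overlap(g1: GECN, g2: GECN, key: str = "ec",
                          expand_partial: bool = False) -> OverlapResult:
    """Overlap structure of two enzyme networks keyed on EC number.

    The overlap graph's nodes are the ECs present in both networks; an edge
    joins two shared ECs iff the pair is adjacent in BOTH networks (under the
    per-network EC collapse). Partial ECs like ``2.4.1.-`` match only by
    exact string equality unless ``expand_partial`` is set, in which case
    each partial is first rewritten to the full ECs (of either network) it
    covers — silent wildcard matching would inflate overlaps, so this is
    opt-in.
    """
    if key != "ec":
        raise ValueError(f"unsupported overlap key {key!r}")
    k1, skipped1 = _ec_collapse(g1)
    k2, skipped2 = _ec_collapse(g2)
    if expand_partial:
        universe = {ec for ec in (*k1.nodes, *k2.nodes) if "-" not in ec}
        k1 = _expand_partials(k1, universe)
        k2 = _expand_partials(k2, universe)
    if skipped1 or skipped2:
        logger.info("overlap: %d + %d node(s) without EC excluded from keying", skipped1, skipped2)
    shared = frozenset(k1.nodes) & frozenset(k2.nodes)
    og = nx.Graph()
    og.add_nodes_from(sorted(shared))
    for u, v in k1.edges:
        if u in shared and v in shared and k2.has_edge(u, v):
            og.add_edge(u, v)
    return OverlapResult(
        shared_ecs=shared,
        graph=og,
        components=connected_components(og),
        unkeyed_nodes=(skipped1, skipped2),
    )


def degree_stats(g: GECN | nx.Graph) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-node degrees (descending, ties by id) and min/median/max summary."""
    graph = g.graph if isinstance(g, GECN) else g
    rows = sorted(((n, graph.degree(n)) for n in graph.nodes), key=lambda t: (-t[1], t[0]))
    table = pd.DataFrame(rows, columns=["node", "degree"])
    if rows:
        degs = [d for _, d in rows]
        summary = {"min": float(min(degs)), "median": float(statistics.median(degs)),
                   "max": float(max(degs))}
    else:
        summary = {"min": float("nan"), "median": float("nan"), "max": float("nan")}
    return table, summary
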