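"""Reconstruction of pathway reaction chains and extraction of maximal
consecutive-step metabolic routes.

A route is an ordered list of reactions in which every consecutive pair is
linked by a non-currency metabolite (a product of the earlier reaction that
is a substrate of the later one) and every step is catalyzed by at least one
enzyme encoded by a differentially expressed gene. Maximal routes cannot be
extended at either end by another qualifying step. Joint DEG status of the
consecutive steps' genes is the package's operational notion of
co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .build import GECN, CurrencySet, default_currency_set
from .degs import DEGSet, SubNetwork, map_degs_to_enzymes
from .pgdb_io import PathwayDB, Reaction

logger = logging.getLogger(__name__)

__all__ = ["ChainStep", "PathwayChain", "RouteStep", "Route", "RouteResult",
           "pathway_chain", "find_maximal_routes", "route_report", "validate_route"]

DEFAULT_MAX_PATHS = 10_000


@dataclass(frozen=True)
class ChainStep:
    reaction_id: str
    ec: str
    enzyme_ids: tuple[str, ...]
    substrates: frozenset[str]
    products: frozenset[str]
    #: non-currency metabolite feeding the next step; None on the last step
    link_to_next: str | None


@dataclass
class PathwayChain:
    """One maximal chain of consecutively linked reactions in a pathway."""

    pathway_id: str
    steps: tuple[ChainStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(s.reaction_id for s in self.steps)

    @property
    def linking_compounds(self) -> tuple[str, ...]:
        return tuple(s.link_to_next for s in self.steps[:-1])


@dataclass(frozen=True)
class RouteStep:
    reaction_id: str
    ec: str
    enzyme_ids: tuple[str, ...]
    #: DEG genes encoding this step's enzymes
    deg_genes: tuple[str, ...]
    link_to_next: str | None


@dataclass
class Route:
    """A DEG-covered consecutive-step metabolic route."""

    steps: tuple[RouteStep, ...]
    pathway_id: str | None = None

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(s.reaction_id for s in self.steps)


@dataclass
class RouteResult:
    routes: list[Route]
    truncated: bool = False

    def __iter__(self):
        return iter(self.routes)

    def __len__(self) -> int:
        return len(self.routes)

    @property
    def longest(self) -> Route | None:
        return self.routes[0] if self.routes else None


# ---------------------------------------------------------------------------
# linking relation between reactions
# ---------------------------------------------------------------------------

def _effective_sides(rxn: Reaction) -> tuple[frozenset[str], frozenset[str]]:
    """(substrates, products) with reversible reactions contributing both."""
    if rxn.reversible:
        both = rxn.substrates | rxn.products
        return both, both
    return rxn.substrates, rxn.products


def _link_compounds(r1: Reaction, r2: Reaction, currency: CurrencySet) -> list[str]:
    _, prods = _effective_sides(r1)
    subs, _ = _effective_sides(r2)
    return sorted(c for c in prods & subs if c not in currency)


def _reaction_graph(db: PathwayDB, reaction_ids: Iterable[str], currency: CurrencySet) -> nx.DiGraph:
    g = nx.DiGraph()
    rids = [r for r in reaction_ids if r in db.reactions]
    g.add_nodes_from(rids)
    for r1 in rids:
        for r2 in rids:
            if r1 == r2:
                continue
            links = _link_compounds(db.reactions[r1], db.reactions[r2], currency)
            if links:
                g.add_edge(r1, r2, compounds=tuple(links))
    return g


# ---------------------------------------------------------------------------
# pathway chains
# ---------------------------------------------------------------------------

def _chain_from_reactions(db: PathwayDB, pathway_id: str, rids: Sequence[str],
                          currency: CurrencySet) -> list[PathwayChain]:
    """Turn an ordered reaction list into chains, splitting where consecutive
    reactions share no non-currency link."""
    chains: list[PathwayChain] = []
    run: list[ChainStep] = []

    def step_for(rid: str, link: str | None) -> ChainStep:
        rxn = db.reactions[rid]
        return ChainStep(rid, rxn.ec, db.enzymes_of_reaction(rid),
                         rxn.substrates, rxn.products, link)

    for i, rid in enumerate(rids):
        link = None
        if i + 1 < len(rids):
            shared = _link_compounds(db.reactions[rid], db.reactions[rids[i + 1]], currency)
            link = shared[0] if shared else None
        run.append(step_for(rid, link))
        if i + 1 < len(rids) and link is None:
            logger.warning("pathway %s: no non-currency link between %s and %s; chain split",
                           pathway_id, rid, rids[i + 1])
            chains.append(PathwayChain(pathway_id, tuple(run)))
            run = []
    if run:
        chains.append(PathwayChain(pathway_id, tuple(run)))
    return chains


def _break_cycles(g: nx.DiGraph, pathway_id: str) -> None:
    """Cut lexicographically smallest back-edges until acyclic."""
    while True:
        sccs = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
        if not sccs:
            return
        cyclic_edges = sorted(
            (u, v) for u, v in g.edges
            if any(u in c and v in c for c in sccs)
        )
        u, v = cyclic_edges[0]
        logger.warning("pathway %s: cycle detected, cutting back-edge %s->%s", pathway_id, u, v)
        g.remove_edge(u, v)


def _maximal_dag_paths(g: nx.DiGraph) -> list[tuple[str, ...]]:
    """All source-to-sink simple paths of a DAG, lexicographically sorted."""
    sources = sorted(n for n in g.nodes if g.in_degree(n) == 0)
    paths: list[tuple[str, ...]] = []
    for src in sources:
        stack: list[tuple[str, tuple[str, ...]]] = [(src, (src,))]
        while stack:
            node, path = stack.pop()
            succs = sorted(g.successors(node), reverse=True)
            if not succs:
                paths.append(path)
            else:
                for s in succs:
                    stack.append((s, path + (s,)))
    return sorted(paths)


def pathway_chain(db: PathwayDB, pathway_id: str, currency: CurrencySet | None = None) -> list[PathwayChain]:
    """Reconstruct the reaction chain(s) of a declared pathway.

    With a declared ``reaction_order`` the chain follows it (splitting, with a
    warning, wherever consecutive reactions share no non-currency compound).
    Otherwise the order is inferred: the pathway's reactions are arranged in
    the DAG of the non-currency product→substrate relation (cycles are cut at
    the lexicographically smallest back-edge, with a warning) and every
    maximal source-to-sink path becomes a chain — a branched pathway thus
    yields a chain cover rather than a single chain. Linking-compound ties
    break lexicographically.
    """
    if pathway_id not in db.pathways:
        raise KeyError(f"unknown pathway {pathway_id!r}")
    if currency is None:
        currency = default_currency_set()
    pw = db.pathways[pathway_id]
    if pw.reaction_order:
        rids = [r for r in pw.reaction_order if r in db.reactions]
        if len(rids) < len(pw.reaction_order):
            logger.warning("pathway %s: %d unknown reaction id(s) in declared order dropped",
                           pathway_id, len(pw.reaction_order) - len(rids))
        return _chain_from_reactions(db, pathway_id, rids, currency)

    members = sorted(r.reaction_id for r in db.reactions.values() if pathway_id in r.pathway_ids)
    g = _reaction_graph(db, members, currency)
    _break_cycles(g, pathway_id)
    return [
        _chain_from_reactions(db, pathway_id, list(path), currency)[0]
        for path in _maximal_dag_paths(g)
    ]


# ---------------------------------------------------------------------------
# maximal DEG-covered routes
# ---------------------------------------------------------------------------

def _is_strict_subpath(a: tuple[str, ...], b: tuple[str, ...]) -> bool:
    if len(a) >= len(b):
        return False
    return any(b[i:i + len(a)] == a for i in range(len(b) - len(a) + 1))


def _drop_subpaths(paths: list[tuple[str, ...]]) -> list[tuple[str, ...]]:
    uniq = sorted(set(paths), key=lambda p: (-len(p), p))
    kept: list[tuple[str, ...]] = []
    for p in uniq:
        if not any(_is_strict_subpath(p, q) for q in kept):
            kept.append(p)
    return kept


def _maximal_simple_paths(g: nx.DiGraph, cap: int) -> tuple[list[tuple[str, ...]], bool]:
    """All maximal simple paths of a (possibly cyclic) directed graph.

    Forward-unextendable paths are enumerated from every start node and
    backward-extendable ones removed as strict sub-paths; exhaustive below
    ``cap`` recorded paths, deterministically truncated above it.
    """
    paths: list[tuple[str, ...]] = []
    truncated = False
    for start in sorted(g.nodes):
        stack: list[tuple[str, tuple[str, ...]]] = [(start, (start,))]
        while stack:
            node, path = stack.pop()
            succs = [s for s in sorted(g.successors(node), reverse=True) if s not in path]
            if not succs:
                paths.append(path)
                if len(paths) >= cap:
                    truncated = True
                    break
            else:
                for s in succs:
                    stack.append((s, path + (s,)))
        if truncated:
            break
    if truncated:
        logger.warning("route enumeration truncated at %d paths", cap)
    return _drop_subpaths(paths), truncated


def _deg_enzyme_map(degs: DEGSet, db: PathwayDB) -> dict[str, tuple[str, ...]]:
    mapping, _ = map_degs_to_enzymes(degs, db)
    return mapping


def _route_from_path(db: PathwayDB, path: tuple[str, ...], currency: CurrencySet,
                     deg_map: dict[str, tuple[str, ...]],
                     pathway_id: str | None = None) -> Route:
    steps: list[RouteStep] = []
    for i, rid in enumerate(path):
        rxn = db.reactions[rid]
        enzymes = db.enzymes_of_reaction(rid)
        genes: list[str] = []
        for e in enzymes:
            for gene in deg_map.get(e, ()):
                if gene not in genes:
                    genes.append(gene)
        link = None
        if i + 1 < len(path):
            shared = _link_compounds(rxn, db.reactions[path[i + 1]], currency)
            link = shared[0] if shared else None
        steps.append(RouteStep(rid, rxn.ec, enzymes, tuple(genes), link))
    return Route(tuple(steps), pathway_id=pathway_id)


def _expression_profiles(degtable: pd.DataFrame) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for row in degtable.itertuples(index=False):
        out.setdefault(str(row.gene_id), {})[str(row.contrast)] = float(row.log2fc)
    return out


def _pair_correlation(genes_a: Sequence[str], genes_b: Sequence[str],
                      profiles: dict[str, dict[str, float]]) -> float | None:
    """Best Pearson correlation of contrast-wise log2fc profiles over all
    gene pairs; None when no pair shares >= 3 contrasts."""
    import math
    best: float | None = None
    for ga in genes_a:
        for gb in genes_b:
            pa, pb = profiles.get(ga, {}), profiles.get(gb, {})
            shared = sorted(set(pa) & set(pb))
            if len(shared) < 3:
                continue
            xs = [pa[c] for c in shared]
            ys = [pb[c] for c in shared]
            mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
            sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
            sy = math.sqrt(sum((y - my) ** 2 for y in ys))
            if sx == 0 or sy == 0:
                continue
            r = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / (sx * sy)
            best = r if best is None else max(best, r)
    return best


def find_maximal_routes(source: SubNetwork | GECN | PathwayChain | Sequence[PathwayChain],
                        degs: DEGSet, db: PathwayDB,
                        currency: CurrencySet | None = None,
                        max_paths: int = DEFAULT_MAX_PATHS,
                        min_len: int = 1,
                        min_correlation: float | None = None,
                        degtable: pd.DataFrame | None = None) -> RouteResult:
    """Extract all maximal DEG-covered consecutive-step routes.

    ``source`` selects the search space: pathway chains restrict routes to
    maximal contiguous runs of DEG-covered steps within each chain, while a
    sub-network or full GECN triggers de-novo enumeration over all reactions
    whose enzymes lie in the (DEG-covered) node set. Routes are simple (no
    repeated reaction), maximal (no returned route is a strict sub-path of
    another), and sorted by length descending, then first reaction id.
    ``max_paths`` caps enumeration; hitting it sets ``truncated``.

    Joint DEG status is the default co-expression notion; setting
    ``min_correlation`` (with ``degtable`` for the profiles) additionally
    requires consecutive steps to carry gene pairs whose contrast-wise
    log2fc profiles correlate at least that strongly (pairs without 3 shared
    contrasts are not penalized).
    """
    if max_paths < 1:
        raise ValueError("max_paths must be >= 1")
    if min_correlation is not None and degtable is None:
        raise ValueError("min_correlation requires degtable")
    if currency is None:
        currency = default_currency_set()
    deg_map = _deg_enzyme_map(degs, db)
    profiles = _expression_profiles(degtable) if min_correlation is not None else {}

    def deg_genes_of(rid: str) -> list[str]:
        return [g for e in db.enzymes_of_reaction(rid) for g in deg_map.get(e, ())]

    def pair_ok(r1: str, r2: str) -> bool:
        if min_correlation is None:
            return True
        r = _pair_correlation(deg_genes_of(r1), deg_genes_of(r2), profiles)
        return r is None or r >= min_correlation

    def covered(rid: str) -> bool:
        return any(e in deg_map for e in db.enzymes_of_reaction(rid))

    truncated = False
    raw: list[tuple[tuple[str, ...], str | None]] = []

    if isinstance(source, (PathwayChain,)) or (
            isinstance(source, (list, tuple)) and all(isinstance(c, PathwayChain) for c in source)):
        chains = [source] if isinstance(source, PathwayChain) else list(source)
        for chain in chains:
            run: list[str] = []
            for step in chain.steps:
                qualifies = any(e in deg_map for e in step.enzyme_ids)
                if qualifies and run and not pair_ok(run[-1], step.reaction_id):
                    raw.append((tuple(run), chain.pathway_id))
                    run = []
                if qualifies:
                    run.append(step.reaction_id)
                else:
                    if run:
                        raw.append((tuple(run), chain.pathway_id))
                    run = []
            if run:
                raw.append((tuple(run), chain.pathway_id))
        if len(raw) > max_paths:
            raw = raw[:max_paths]
            truncated = True
    else:
        node_set = source.nodes if isinstance(source, SubNetwork) else set(source.graph.nodes)
        rids = [rid for rid in db.reactions
                if covered(rid) and any(e in node_set for e in db.enzymes_of_reaction(rid))]
        g = _reaction_graph(db, rids, currency)
        if min_correlation is not None:
            g.remove_edges_from([(u, v) for u, v in list(g.edges) if not pair_ok(u, v)])
        paths, truncated = _maximal_simple_paths(g, max_paths)
        raw = [(p, None) for p in paths]

    by_path = {p: pid for p, pid in reversed(raw)}
    kept = _drop_subpaths(list(by_path))
    routes = [_route_from_path(db, p, currency, deg_map, by_path.get(p)) for p in kept
              if len(p) >= min_len]
    routes.sort(key=lambda r: (-r.length, r.reaction_ids))
    return RouteResult(routes, truncated)


def validate_route(route: Route, degs: DEGSet, db: PathwayDB,
                   currency: CurrencySet | None = None) -> None:
    """Check the route invariants; raise ValueError on violation."""
    if currency is None:
        currency = default_currency_set()
    rids = route.reaction_ids
    if len(set(rids)) != len(rids):
        raise ValueError("route repeats a reaction")
    deg_map = _deg_enzyme_map(degs, db)
    for i, step in enumerate(route.steps):
        if not any(e in deg_map for e in step.enzyme_ids):
            raise ValueError(f"step {step.reaction_id} has no DEG-encoded enzyme")
        if i + 1 < len(route.steps):
            link = step.link_to_next
            if link is None or link in currency:
                raise ValueError(f"step {step.reaction_id}: invalid linking compound {link!r}")
            shared = _link_compounds(db.reactions[step.reaction_id],
                                     db.reactions[route.steps[i + 1].reaction_id], currency)
            if link not in shared:
                raise ValueError(f"step {step.reaction_id}: {link!r} does not link to the next step")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def route_report(route: Route, degtable: pd.DataFrame) -> pd.DataFrame:
    """Tabulate a route: one row per (step, gene) with the gene's strongest
    DE evidence (smallest FDR, then largest |log2fc|).

    Genes missing from ``degtable`` get blank statistics and a warning.
    Columns: step, reaction_id, ec, enzyme_id, gene_id, contrast, log2fc,
    fdr, link_to_next.
    """
    rows = []
    for i, step in enumerate(route.steps, 1):
        genes = step.deg_genes or ()
        for gene in genes:
            hit = degtable.loc[degtable["gene_id"] == gene]
            enzyme = next((e for e in step.enzyme_ids), "")
            if hit.empty:
                logger.warning("route_report: gene %s absent from DEG table", gene)
                contrast, lfc, fdr = "", float("nan"), float("nan")
            else:
                best = hit.sort_values(["fdr", "log2fc"], key=lambda s: s if s.name == "fdr" else -s.abs(),
                                       kind="mergesort").iloc[0]
                contrast, lfc, fdr = best["contrast"], float(best["log2fc"]), float(best["fdr"])
            rows.append((i, step.reaction_id, step.ec, enzyme, gene, contrast, lfc, fdr,
                         step.link_to_next or ""))
    return pd.DataFrame(rows, columns=["step", "reaction_id", "ec", "enzyme_id", "gene_id",
                                       "contrast", "log2fc", "fdr", "link_to_next"])
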