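"""Shared builders for hand-made pathway databases and toy networks."""

from __future__ import annotations

from typing import Iterable, Sequence

import pytest

from gecn.pgdb_io import Compound, Enzyme, PathwayDB, Pathway, Reaction


def build_db(rxns: Sequence[tuple], enzymes: Sequence[tuple] = (),
             gene_enzyme: Sequence[tuple[str, str]] = (),
             pathways: Sequence[tuple] = ()) -> PathwayDB:
    """Assemble a PathwayDB from compact tuples.

    rxns: (rid, ec, substrates, products[, reversible[, enzyme_ids]])
    enzymes: (eid, ec[, name]); gene_enzyme: (gene, eid);
    pathways: (pwid, name[, reaction_order])
    """
    db = PathwayDB()
    for spec in enzymes:
        eid, ec, *rest = spec
        db.enzymes[eid] = Enzyme(eid, ec, rest[0] if rest else "")
    for spec in rxns:
        rid, ec, subs, prods, *rest = spec
        reversible = bool(rest[0]) if rest else False
        enzyme_ids = tuple(rest[1]) if len(rest) > 1 else ()
        for cid in (*subs, *prods):
            db.compounds.setdefault(cid, Compound(cid))
        db.reactions[rid] = Reaction(rid, ec, frozenset(subs), frozenset(prods),
                                     reversible=reversible, enzyme_ids=enzyme_ids)
    db.gene_enzyme.extend(gene_enzyme)
    for spec in pathways:
        pwid, name, *rest = spec
        order = tuple(rest[0]) if rest else ()
        db.pathways[pwid] = Pathway(pwid, name, order)
        for rid in order:
            rxn = db.reactions[rid]
            db.reactions[rid] = Reaction(rid, rxn.ec, rxn.substrates, rxn.products,
                                         rxn.reversible, rxn.pathway_ids | {pwid},
                                         rxn.enzyme_ids)
    db.validate()
    return db


@pytest.fixture
def coupling_toy_db() -> PathwayDB:
    """Two enzymes coupled through compound A: E1 makes {A, B} from X, E2
    consumes A to make C."""
    return build_db(
        rxns=[("RXN-1", "1.1.1.1", ["X"], ["A", "B"], False, ["E1"]),
              ("RXN-2", "2.2.2.2", ["A"], ["C"], False, ["E2"])],
        enzymes=[("E1", "1.1.1.1"), ("E2", "2.2.2.2")],
        gene_enzyme=[("G1", "E1"), ("G2", "E2")],
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def oracle_enzyme_reactions(db: PathwayDB) -> dict[str, list]:
    """Reactions attributed to each enzyme: explicit link or exact EC match."""
    out: dict[str, list] = {}
    for eid, enz in db.enzymes.items():
        out[eid] = [r for r in db.reactions.values()
                    if eid in r.enzyme_ids or (enz.ec != "" and r.ec == enz.ec)]
    return out


def oracle_edge_set(db: PathwayDB, currency: Iterable[str]) -> dict[tuple[str, str], set[str]]:
    """Exhaustive ordered-pair scan of the enzyme-coupling rule."""
    cur = {c.strip().casefold() for c in currency}
    attributed = oracle_enzyme_reactions(db)
    edges: dict[tuple[str, str], set[str]] = {}
    for e1 in db.enzymes:
        for e2 in db.enzymes:
            if e1 == e2:
                continue
            links: set[str] = set()
            for r1 in attributed[e1]:
                prods = set(r1.products) | (set(r1.substrates) if r1.reversible else set())
                for r2 in attributed[e2]:
                    subs = set(r2.substrates) | (set(r2.products) if r2.reversible else set())
                    links |= {c for c in prods & subs if c.strip().casefold() not in cur}
            if links:
                edges[(e1, e2)] = links
    return edges


def oracle_bfs_components(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> list[set[str]]:
    """Hand-rolled BFS labeling."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in adj:
        if start in seen:
            continue
        queue, comp = [start], {start}
        seen.add(start)
        while queue:
            node = queue.pop(0)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    comp.add(nbr)
                    queue.append(nbr)
        comps.append(comp)
    return comps


def oracle_all_simple_maximal_paths(nodes: Sequence[str],
                                    edges: set[tuple[str, str]]) -> set[tuple[str, ...]]:
    """All maximal simple paths by exhaustive extension from every path."""
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    pred: dict[str, list[str]] = {n: [] for n in nodes}
    for u, v in edges:
        succ[u].append(v)
        pred[v].append(u)
    all_paths: set[tuple[str, ...]] = set()

    def grow(path: tuple[str, ...]) -> None:
        extended = False
        for s in succ[path[-1]]:
            if s not in path:
                extended = True
                grow(path + (s,))
        for p in pred[path[0]]:
            if p not in path:
                extended = True
                grow((p,) + path)
        if not extended:
            all_paths.add(path)

    for n in nodes:
        grow((n,))
    return all_paths
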