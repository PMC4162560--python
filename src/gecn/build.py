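"""Construction of genome-scale enzyme correlation networks (GECN).

Enzymes are nodes. A directed edge runs from enzyme E1 to enzyme E2 whenever
some product of a reaction catalyzed by E1 is a substrate of a reaction
catalyzed by E2 and that shared compound is not a currency metabolite.
Reversible reactions contribute both orientations of their substrate/product
sets. Currency metabolites — ubiquitous carriers such as ATP, NAD(P)(H), CoA,
O2 or CO2 that would connect nearly every enzyme pair — are excluded as
linking compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .pgdb_io import PathwayDB

logger = logging.getLogger(__name__)

__all__ = ["CurrencySet", "default_currency_set", "GECN", "build_gecn", "collapse_to_undirected"]

#: Ubiquitous small molecules excluded as linking metabolites. "NADH" is kept
#: alongside "ADH": the latter token circulates in some currency lists but
#: reads as alcohol dehydrogenase — an enzyme, not a metabolite — so it is
#: treated as a variant spelling of NADH and both are excluded by default.
#: "Glu"/"L-glutamate" are excluded only in their role as linking compounds
#: (chain endpoints are unaffected). Callers may replace or extend the set.
DEFAULT_CURRENCY_TOKENS = (
    "H+", "ADH", "NADP", "NADPH", "NH3", "ATP", "ADP", "AMP", "NAD",
    "CoA", "O2", "CO2", "Glu", "pyrophosphate", "NADH", "L-glutamate",
)


class CurrencySet:
    """Set of currency-metabolite tokens with exact, case-insensitive matching.

    Matching is by whole normalized token: "CoA" is currency, "acetyl-CoA"
    is not.
    """

    def __init__(self, tokens: Iterable[str] = ()) -> None:
        self._display: dict[str, str] = {}
        for tok in tokens:
            self.add(tok)

    @staticmethod
    def _norm(token: str) -> str:
        return token.strip().casefold()

    def add(self, token: str) -> None:
        tok = token.strip()
        if tok:
            self._display.setdefault(self._norm(tok), tok)

    def __contains__(self, token: str) -> bool:
        return self._norm(token) in self._display

    def __iter__(self) -> Iterator[str]:
        return iter(self._display.values())

    def __len__(self) -> int:
        return len(self._display)

    def __or__(self, other: "CurrencySet | Iterable[str]") -> "CurrencySet":
        return CurrencySet([*self, *other])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CurrencySet({sorted(self._display.values())!r})"


def default_currency_set() -> CurrencySet:
    """The default currency metabolites (see DEFAULT_CURRENCY_TOKENS)."""
    return CurrencySet(DEFAULT_CURRENCY_TOKENS)


@dataclass
class GECN:
    """Enzyme correlation network.

    ``graph`` is a networkx DiGraph (directed view) or Graph (undirected
    view). Nodes are enzyme ids with ``ec`` and ``genes`` attributes; each
    edge carries ``compounds``, the non-empty frozenset of linking
    metabolites. Simple graph: at most one edge per (ordered) pair.
    """

    graph: nx.DiGraph | nx.Graph
    directed: bool = True

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_compounds(self, u: str, v: str) -> frozenset[str]:
        return self.graph.edges[u, v]["compounds"]

    def sif_edges(self, relation: str = "cc") -> list[tuple[str, str, str]]:
        """Edges as SIF triples, deterministically ordered."""
        if self.directed:
            items = sorted(self.graph.edges)
        else:
            items = sorted(tuple(sorted(e)) for e in self.graph.edges)
        return [(u, relation, v) for u, v in items]

    def validate(self, currency: CurrencySet | None = None) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if not data["compounds"]:
                raise ValueError(f"edge {u}->{v} without linking compounds")
            if currency is not None:
                for c in data["compounds"]:
                    if c in currency:
                        raise ValueError(f"edge {u}->{v} links via currency metabolite {c}")


def _orientations(rxn) -> list[tuple[frozenset[str], frozenset[str]]]:
    out = [(rxn.substrates, rxn.products)]
    if rxn.reversible:
        out.append((rxn.products, rxn.substrates))
    return out


def build_gecn(db: PathwayDB, currency: CurrencySet | None = None, directed: bool = True) -> GECN:
    """Build the enzyme correlation network of a pathway database.

    Every enzyme becomes a node (degree-0 enzymes are retained and logged).
    For each ordered pair (E1, E2) of distinct enzymes, an edge E1→E2 exists
    iff some product of a reaction of E1 equals some substrate of a reaction
    of E2 and the compound is not in ``currency``; the linking compounds are
    recorded on the edge. With ``directed=False`` the two orientations are
    merged and linking sets unioned.
    """
    if currency is None:
        currency = default_currency_set()

    g = nx.DiGraph()
    for enzyme in db.enzymes.values():
        g.add_node(enzyme.enzyme_id, ec=enzyme.ec, genes=db.genes_of_enzyme(enzyme.enzyme_id))

    # compound -> producing / consuming enzymes, skipping currency up front
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rxn in db.reactions.values():
        enzymes = db.enzymes_of_reaction(rxn.reaction_id)
        if not enzymes:
            continue
        for subs, prods in _orientations(rxn):
            for c in prods:
                if c not in currency:
                    producers.setdefault(c, set()).update(enzymes)
            for c in subs:
                if c not in currency:
                    consumers.setdefault(c, set()).update(enzymes)

    for compound, prod_enzymes in producers.items():
        for e1 in prod_enzymes:
            for e2 in consumers.get(compound, ()):
                if e1 == e2:
                    continue
                if g.has_edge(e1, e2):
                    g.edges[e1, e2]["compounds"] = g.edges[e1, e2]["compounds"] | {compound}
                else:
                    g.add_edge(e1, e2, compounds=frozenset({compound}))

    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if isolated:
        logger.info("%d enzyme(s) with no coupling retained at degree 0", len(isolated))

    net = GECN(g, directed=True)
    return net if directed else collapse_to_undirected(net)


def collapse_to_undirected(net: GECN) -> GECN:
    """Merge edge orientations; linking-compound sets are unioned."""
    if not net.directed:
        return net
    ug = nx.Graph()
    ug.add_nodes_from(net.graph.nodes(data=True))
    for u, v, data in net.graph.edges(data=True):
        if ug.has_edge(u, v):
            ug.edges[u, v]["compounds"] = ug.edges[u, v]["compounds"] | data["compounds"]
        else:
            ug.add_edge(u, v, compounds=data["compounds"])
    return GECN(ug, directed=False)
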