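"""Pathway-chain reconstruction and maximal DEG-covered route extraction."""

from __future__ import annotations

import itertools
import random

import pandas as pd
import pytest

from gecn.build import CurrencySet, build_gecn, default_currency_set
from gecn.degs import call_degs, induce_subnetwork, map_degs_to_enzymes
from gecn.fixtures import paper_fixture
from gecn.pgdb_io import Pathway
from gecn.routes import (find_maximal_routes, pathway_chain, route_report,
                         validate_route)

from conftest import build_db, oracle_all_simple_maximal_paths


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "fdr"])


def _all_degs(db):
    return call_degs(_table([(g, "c", 2.0, 1e-12) for g, _ in db.gene_enzyme]))


# ---------------------------------------------------------------------------
# pathway chains
# ---------------------------------------------------------------------------


def test_ethanol_degradation_chain():
    fx = paper_fixture("fig5_ethanol_degradation_II")
    chains = pathway_chain(fx.db, fx.pathway_id)
    assert len(chains) == 1
    chain = chains[0]
    assert len(chain) == 3
    assert chain.linking_compounds == ("acetaldehyde", "acetate")


def test_single_reaction_pathway_chain():
    db = build_db(
        rxns=[("R1", "1.1.1.1", ["x"], ["y"], False, ["E1"])],
        enzymes=[("E1", "1.1.1.1")],
        pathways=[("PWY", "solo", ["R1"])],
    )
    chains = pathway_chain(db, "PWY")
    assert len(chains) == 1 and len(chains[0]) == 1
    assert chains[0].linking_compounds == ()


def test_unknown_pathway_raises():
    fx = paper_fixture("fig5_ethanol_degradation_II")
    with pytest.raises(KeyError):
        pathway_chain(fx.db, "NO-SUCH-PWY")


def _random_dag_pathway_db(seed, n):
    """Reactions linked along a random DAG via dedicated compounds."""
    rng = random.Random(seed)
    rids = [f"R{i:02d}" for i in range(n)]
    edges = set()
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.25:
            edges.add((i, j))
    rxns = []
    compounds_in = {i: {f"start{i}"} for i in range(n)}
    compounds_out = {i: {f"end{i}"} for i in range(n)}
    for i, j in edges:
        compounds_out[i].add(f"link{i}-{j}")
        compounds_in[j].add(f"link{i}-{j}")
    for i in range(n):
        rxns.append((rids[i], "", sorted(compounds_in[i]), sorted(compounds_out[i]),
                     False, [f"E{i:02d}"]))
    db = build_db(rxns, enzymes=[(f"E{i:02d}", "") for i in range(n)],
                  gene_enzyme=[(f"G{i:02d}", f"E{i:02d}") for i in range(n)],
                  pathways=[("PWY", "dag")])
    for rid in rids:
        rxn = db.reactions[rid]
        db.reactions[rid] = type(rxn)(rxn.reaction_id, rxn.ec, rxn.substrates,
                                      rxn.products, rxn.reversible,
                                      frozenset({"PWY"}), rxn.enzyme_ids)
    return db, edges, rids


@pytest.mark.parametrize("seed", range(12))
def test_inferred_chain_cover_equals_exhaustive_path_enumeration(seed):
    db, edges, rids = _random_dag_pathway_db(seed, n=9)
    chains = pathway_chain(db, "PWY", CurrencySet())
    got = {c.reaction_ids for c in chains}
    # oracle: exhaustive maximal-path enumeration over the DAG
    named_edges = {(rids[i], rids[j]) for i, j in edges}
    want = oracle_all_simple_maximal_paths(rids, named_edges)
    assert got == want


def test_cyclic_pathway_cut_at_smallest_back_edge(caplog):
    db = build_db(
        rxns=[("RA", "", ["x"], ["a"], False, ["E1"]),
              ("RB", "", ["a"], ["b"], False, ["E2"]),
              ("RC", "", ["b"], ["a2"], False, ["E3"])],
        enzymes=[("E1", ""), ("E2", ""), ("E3", "")],
    )
    # close a cycle RB -> RC -> RB by letting RC feed RB
    rxn = db.reactions["RC"]
    db.reactions["RC"] = type(rxn)("RC", "", frozenset({"b"}), frozenset({"a"}),
                                   False, frozenset({"PWY"}), ("E3",))
    for rid in ("RA", "RB"):
        r = db.reactions[rid]
        db.reactions[rid] = type(r)(r.reaction_id, r.ec, r.substrates, r.products,
                                    False, frozenset({"PWY"}), r.enzyme_ids)
    db.pathways["PWY"] = Pathway("PWY", "cyclic")
    with caplog.at_level("WARNING"):
        chains = pathway_chain(db, "PWY", CurrencySet())
    assert any("cycle" in r.message for r in caplog.records)
    assert chains  # still yields a chain cover
    for c in chains:
        assert len(set(c.reaction_ids)) == len(c.reaction_ids)


def test_declared_order_splits_on_missing_link(caplog):
    db = build_db(
        rxns=[("R1", "", ["x"], ["a"], False, ["E1"]),
              ("R2", "", ["q"], ["w"], False, ["E2"])],
        enzymes=[("E1", ""), ("E2", "")],
        pathways=[("PWY", "broken", ["R1", "R2"])],
    )
    with caplog.at_level("WARNING"):
        chains = pathway_chain(db, "PWY", CurrencySet())
    assert [c.reaction_ids for c in chains] == [("R1",), ("R2",)]


# ---------------------------------------------------------------------------
# maximal routes
# ---------------------------------------------------------------------------


def test_tca_variation_single_maximal_route():
    fx = paper_fixture("fig6_tca_variation")
    degs = call_degs(fx.deg_table)
    routes = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db)
    assert len(routes) == 1
    assert routes.longest.length == 4
    validate_route(routes.longest, degs, fx.db)


def test_glycolysis_aldolase_gap_shortens_route_to_five():
    fx = paper_fixture("fig7_glycolysis_IV")
    degs = call_degs(fx.deg_table)
    chains = pathway_chain(fx.db, fx.pathway_id)
    assert len(chains[0]) == 7
    routes = find_maximal_routes(chains, degs, fx.db)
    assert routes.longest.length == 5
    assert routes.longest.reaction_ids == tuple(f"GLYC-IV-RXN-{i}" for i in range(3, 8))


def test_routes_are_mutually_maximal():
    fx = paper_fixture("fig10_pa_biosynthesis")
    degs = call_degs(fx.deg_table)
    routes = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db)
    seqs = [r.reaction_ids for r in routes]
    for a in seqs:
        for b in seqs:
            if a is b:
                continue
            assert not any(b[i:i + len(a)] == a for i in range(len(b) - len(a) + 1)), \
                f"{a} is a sub-path of {b}"


def test_truncation_is_flagged_never_silent():
    fx = paper_fixture("fig10_pa_biosynthesis")
    degs = call_degs(fx.deg_table)
    result = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db,
                                 max_paths=1)
    assert result.truncated
    assert len(result) >= 1


@pytest.mark.parametrize("seed", range(10))
def test_de_novo_routes_equal_exhaustive_simple_path_search(seed):
    db, edges, rids = _random_dag_pathway_db(seed + 100, n=8)
    degs = _all_degs(db)
    net = build_gecn(db, CurrencySet(), directed=False)
    mapping, _ = map_degs_to_enzymes(degs, db)
    sub = induce_subnetwork(net, mapping, drop_isolated=False)
    result = find_maximal_routes(sub, degs, db, CurrencySet())
    assert not result.truncated
    named_edges = {(rids[i], rids[j]) for i, j in edges}
    want = oracle_all_simple_maximal_paths(rids, named_edges)
    assert {r.reaction_ids for r in result} == want
    for r in result:
        validate_route(r, degs, db, CurrencySet())


@pytest.mark.parametrize("seed", range(6))
def test_adding_degs_never_shortens_longest_route(seed):
    db, _, rids = _random_dag_pathway_db(seed + 50, n=8)
    rng = random.Random(seed)
    genes = [g for g, _ in db.gene_enzyme]
    some = set(rng.sample(genes, 4))
    more = some | set(rng.sample(genes, 3))
    chains = pathway_chain(db, "PWY", CurrencySet())

    def longest(gene_subset):
        degs = call_degs(_table([(g, "c", 2.0, 1e-12) for g in gene_subset]))
        res = find_maximal_routes(chains, degs, db, CurrencySet())
        return res.longest.length if res.longest else 0

    assert longest(more) >= longest(some)


def test_min_correlation_filter_splits_anticorrelated_steps():
    fx = paper_fixture("fig5_ethanol_degradation_II")
    # three contrasts: step-2 gene moves opposite to its neighbors
    rows = []
    for gene, sign in [("AT5G63620", 1), ("AT1G54100", -1), ("AT5G36880", 1)]:
        for i, c in enumerate(["t1", "t2", "t3"]):
            rows.append((gene, c, sign * (1.5 + i), 1e-12))
    table = _table(rows)
    degs = call_degs(table)
    chains = pathway_chain(fx.db, fx.pathway_id)
    plain = find_maximal_routes(chains, degs, fx.db)
    assert plain.longest.length == 3
    filtered = find_maximal_routes(chains, degs, fx.db, min_correlation=0.5,
                                   degtable=table)
    assert filtered.longest.length == 1
    assert len(filtered) == 3


# ---------------------------------------------------------------------------
# route reports
# ---------------------------------------------------------------------------


def test_ethanol_route_report_rows():
    fx = paper_fixture("fig5_ethanol_degradation_II")
    degs = call_degs(fx.deg_table)
    routes = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db)
    rep = route_report(routes.longest, fx.deg_table)
    assert list(rep["gene_id"]) == ["AT5G63620", "AT1G54100", "AT5G36880"]
    assert list(rep["ec"]) == ["1.1.1.1", "1.2.1.3", "6.2.1.1"]
    assert list(rep["link_to_next"]) == ["acetaldehyde", "acetate", ""]


def test_report_row_count_is_sum_of_step_gene_counts():
    fx = paper_fixture("fig8_kaempferol")
    degs = call_degs(fx.deg_table)
    routes = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db)
    route = routes.longest
    rep = route_report(route, fx.deg_table)
    assert len(rep) == sum(len(s.deg_genes) for s in route.steps)


def test_report_missing_gene_gets_blank_stats(caplog):
    fx = paper_fixture("fig5_ethanol_degradation_II")
    degs = call_degs(fx.deg_table)
    routes = find_maximal_routes(pathway_chain(fx.db, fx.pathway_id), degs, fx.db)
    stripped = fx.deg_table[fx.deg_table["gene_id"] != "AT1G54100"]
    with caplog.at_level("WARNING"):
        rep = route_report(routes.longest, stripped)
    row = rep[rep["gene_id"] == "AT1G54100"].iloc[0]
    assert row["contrast"] == ""
    assert pd.isna(row["fdr"])
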