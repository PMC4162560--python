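"""Flat-file, TSV-bundle, DEG, PPI and SIF input/output."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from gecn.pgdb_io import (
    PGDBFormatError,
    export_tsv_bundle,
    load_deg_table,
    load_pathway_db,
    load_ppi,
    parse_attribute_value,
    read_sif,
    serialize_attribute_value,
    write_sif,
)

from conftest import build_db

# ---------------------------------------------------------------------------
# attribute-value parsing
# ---------------------------------------------------------------------------


def test_parse_empty_file(tmp_path):
    p = tmp_path / "empty.dat"
    p.write_text("")
    assert parse_attribute_value(p) == []


def test_parse_minimal_record(tmp_path):
    p = tmp_path / "one.dat"
    p.write_text("UNIQUE-ID - RXN-1\nEC-NUMBER - 1.1.1.1\n//\n")
    recs = parse_attribute_value(p)
    assert len(recs) == 1
    assert recs[0].record_id == "RXN-1"
    assert recs[0].all("EC-NUMBER") == ["1.1.1.1"]


def test_parse_continuation_comment_and_malformed(tmp_path):
    p = tmp_path / "messy.dat"
    p.write_text(
        "# a comment\n"
        "UNIQUE-ID - CPD-1\n"
        "COMMENT - first part\n"
        "/second part\n"
        "BROKEN LINE WITHOUT SEPARATOR\n"
        "//\n"
        "NO-ID-HERE - x\n"
        "//\n"
    )
    recs = parse_attribute_value(p)
    assert len(recs) == 1  # block without UNIQUE-ID skipped
    assert recs[0].all("COMMENT") == ["first part second part"]


def _naive_reference_parse(text: str) -> list[tuple[str, list[tuple[str, str]]]]:
    """Independent line-by-line interpreter splitting on // blocks."""
    out = []
    for block in text.split("//\n"):
        pairs = []
        for line in block.splitlines():
            if line.startswith("#") or not line.strip():
                continue
            if line.startswith("/"):
                name, val = pairs[-1]
                pairs[-1] = (name, (val + " " + line[1:].strip()).strip())
                continue
            if " - " in line:
                name, val = line.split(" - ", 1)
                pairs.append((name.strip().upper(), val.strip()))
        ids = [v for n, v in pairs if n == "UNIQUE-ID"]
        if ids:
            out.append((ids[0], pairs))
    return out


def test_parse_matches_reference_interpreter(tmp_path):
    rng = random.Random(7)
    names = ["UNIQUE-ID", "EC-NUMBER", "LEFT", "RIGHT", "COMMON-NAME", "SYNONYMS"]
    lines = []
    for i in range(60):
        lines.append(f"UNIQUE-ID - REC-{i}")
        for _ in range(rng.randrange(0, 6)):
            lines.append(f"{rng.choice(names[1:])} - value-{rng.randrange(100)}")
        lines.append("//")
    text = "\n".join(lines) + "\n"
    p = tmp_path / "rand.dat"
    p.write_text(text)
    got = [(r.record_id, [(n, v) for n, vs in r.attributes.items() for v in vs])
           for r in parse_attribute_value(p)]
    want = [(rid, pairs) for rid, pairs in _naive_reference_parse(text)]
    # compare as multisets of (record, attr, value) preserving per-attr order
    assert [rid for rid, _ in got] == [rid for rid, _ in want]
    for (_, gp), (_, wp) in zip(got, want):
        assert sorted(gp) == sorted(wp)


def test_serialize_reparse_fixed_point(tmp_path):
    p = tmp_path / "a.dat"
    p.write_text("UNIQUE-ID - R1\nLEFT - x\nLEFT - y\nRIGHT - z\n//\n")
    recs = parse_attribute_value(p)
    text = serialize_attribute_value(recs)
    q = tmp_path / "b.dat"
    q.write_text(text)
    recs2 = parse_attribute_value(q)
    assert [(r.record_id, r.attributes) for r in recs] == \
           [(r.record_id, r.attributes) for r in recs2]
    assert serialize_attribute_value(recs2) == text


# ---------------------------------------------------------------------------
# pathway-database bundles
# ---------------------------------------------------------------------------


def test_load_coupling_toy_bundle(tmp_path, coupling_toy_db):
    export_tsv_bundle(coupling_toy_db, tmp_path)
    db = load_pathway_db(tmp_path)
    assert len(db.enzymes) == 2
    assert len(db.reactions) == 2
    assert len(db.compounds) == 4
    assert db.reactions["RXN-1"].products == frozenset({"A", "B"})


def test_unknown_compound_auto_registered(tmp_path, coupling_toy_db, caplog):
    export_tsv_bundle(coupling_toy_db, tmp_path)
    rxn_file = tmp_path / "reactions.tsv"
    content = rxn_file.read_text().replace("A;B", "A;B;Q")
    rxn_file.write_text(content)
    with caplog.at_level("WARNING"):
        db = load_pathway_db(tmp_path)
    assert "Q" in db.compounds
    assert db.compounds["Q"].name == ""
    assert "RXN-1" in db.reactions
    assert any("auto-registered" in r.message for r in caplog.records)


def test_missing_file_and_column_errors(tmp_path, coupling_toy_db):
    export_tsv_bundle(coupling_toy_db, tmp_path)
    (tmp_path / "enzymes.tsv").unlink()
    with pytest.raises(PGDBFormatError, match="enzymes.tsv"):
        load_pathway_db(tmp_path)
    export_tsv_bundle(coupling_toy_db, tmp_path)
    (tmp_path / "reactions.tsv").write_text("reaction_id\tsubstrates\nR\tx\n")
    with pytest.raises(PGDBFormatError, match="ec"):
        load_pathway_db(tmp_path)


def test_load_is_idempotent_on_export(tmp_path):
    from gecn.fixtures import FixtureSpec, make_random_pgdb
    db = make_random_pgdb(FixtureSpec(seed=11, n_reactions=15, n_enzymes=12, n_genes=20))
    d1, d2 = tmp_path / "one", tmp_path / "two"
    export_tsv_bundle(db, d1)
    db2 = load_pathway_db(d1)
    export_tsv_bundle(db2, d2)
    for fname in ("compounds.tsv", "reactions.tsv", "enzymes.tsv", "gene_enzyme.tsv"):
        assert (d1 / fname).read_bytes() == (d2 / fname).read_bytes()


def test_load_attribute_value_directory(tmp_path):
    (tmp_path / "compounds.dat").write_text(
        "UNIQUE-ID - X\n//\nUNIQUE-ID - A\n//\nUNIQUE-ID - C\n//\n")
    (tmp_path / "reactions.dat").write_text(
        "UNIQUE-ID - RXN-1\nEC-NUMBER - 1.1.1.1\nLEFT - X\nRIGHT - A\n//\n"
        "UNIQUE-ID - RXN-2\nEC-NUMBER - 2.2.2.2\nLEFT - A\nRIGHT - C\n"
        "REACTION-DIRECTION - REVERSIBLE\n//\n")
    (tmp_path / "proteins.dat").write_text(
        "UNIQUE-ID - E1\nEC-NUMBER - 1.1.1.1\nCATALYZES - RXN-1\n//\n"
        "UNIQUE-ID - E2\nEC-NUMBER - 2.2.2.2\nCATALYZES - RXN-2\n//\n")
    (tmp_path / "genes.dat").write_text(
        "UNIQUE-ID - G1\nPRODUCT - E1\n//\n"
        "UNIQUE-ID - G2\nPRODUCT - E2\nPRODUCT - MISSING-ENZ\n//\n")
    db = load_pathway_db(tmp_path)
    assert set(db.enzymes) == {"E1", "E2"}
    assert db.reactions["RXN-2"].reversible
    assert ("G2", "E2") in db.gene_enzyme
    assert all(e in db.enzymes for _, e in db.gene_enzyme)


def test_compound_resolution_is_case_insensitive(tmp_path, coupling_toy_db):
    export_tsv_bundle(coupling_toy_db, tmp_path)
    rxn_file = tmp_path / "reactions.tsv"
    rxn_file.write_text(rxn_file.read_text().replace("\tA\t", "\ta\t"))
    db = load_pathway_db(tmp_path)
    assert db.reactions["RXN-2"].substrates == frozenset({"A"})


# ---------------------------------------------------------------------------
# DEG, PPI and SIF
# ---------------------------------------------------------------------------


def test_deg_table_skips_bad_rows_and_checks_range(tmp_path, caplog):
    p = tmp_path / "deg.tsv"
    p.write_text("gene_id\tcontrast\tlog2fc\tfdr\n"
                 "g1\tc1\t2.0\t1e-12\n"
                 "g2\tc1\t\t0.5\n")
    with caplog.at_level("WARNING"):
        df = load_deg_table(p)
    assert list(df["gene_id"]) == ["g1"]
    p.write_text("gene_id\tcontrast\tlog2fc\tfdr\ng1\tc1\t2.0\t1.5\n")
    with pytest.raises(PGDBFormatError, match="fdr"):
        load_deg_table(p)
    p.write_text("gene_id\tcontrast\tlog2fc\tfdr\ng1\tc1\t2.0\t0.5\ng1\tc1\t1.0\t0.1\n")
    with pytest.raises(PGDBFormatError, match="duplicate"):
        load_deg_table(p)


def test_ppi_dedup_both_orders_and_self_pairs(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("AT3G14790 AT5G14180\nAT5G14180 AT3G14790\nAT1G01010 AT1G01010\n")
    ppi = load_ppi(p)
    assert len(ppi) == 1
    assert ("AT3G14790", "AT5G14180") in ppi
    assert ("AT5G14180", "AT3G14790") in ppi


def test_ppi_bad_line(tmp_path):
    p = tmp_path / "ppi.txt"
    p.write_text("A B C\n")
    with pytest.raises(PGDBFormatError, match=":1"):
        load_ppi(p)


def test_sif_roundtrip_single_edge(tmp_path):
    path = tmp_path / "net.sif"
    edges = [("E1", "cc", "E2")]
    write_sif(edges, path)
    assert read_sif(path) == edges


def test_sif_bad_token_count(tmp_path):
    path = tmp_path / "bad.sif"
    path.write_text("A cc\n")
    with pytest.raises(PGDBFormatError, match=":1"):
        read_sif(path)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.sampled_from([f"N{i}" for i in range(30)]),
              st.sampled_from(["cc", "pp", "shared"]),
              st.sampled_from([f"N{i}" for i in range(30)])),
    max_size=200))
def test_sif_roundtrip_is_identity_on_edge_multisets(tmp_path_factory, edges):
    path = tmp_path_factory.mktemp("sif") / "net.sif"
    write_sif(edges, path)
    assert sorted(read_sif(path)) == sorted(edges)
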