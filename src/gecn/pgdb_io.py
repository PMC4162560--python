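"""Readers and writers for pathway-genome-database (PGDB) content.

Two on-disk dialects are supported for pathway databases:

* the BioCyc/PlantCyc attribute-value flat-file dump (``reactions.dat``,
  ``compounds.dat``, ``proteins.dat``/``enzymes.dat``, ``genes.dat``,
  optionally ``pathways.dat``), and
* a canonical tab-separated bundle (``compounds.tsv``, ``reactions.tsv``,
  ``enzymes.tsv``, ``gene_enzyme.tsv``, optionally ``pathways.tsv``) that is
  this package's ground-truth schema; the attribute-value reader maps onto it.

Also here: DEG tables (gene, contrast, log2 fold change, FDR), binary
protein-protein interaction edge lists, and Cytoscape SIF network files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PGDBFormatError",
    "AttributeValueRecord",
    "Compound",
    "Reaction",
    "Enzyme",
    "Pathway",
    "PathwayDB",
    "PPIEdgeList",
    "parse_attribute_value",
    "serialize_attribute_value",
    "load_pathway_db",
    "export_tsv_bundle",
    "load_deg_table",
    "write_deg_table",
    "load_ppi",
    "write_sif",
    "read_sif",
]

DEG_COLUMNS = ("gene_id", "contrast", "log2fc", "fdr")


class PGDBFormatError(ValueError):
    """A mandatory file or column is missing, or a line is unparseable."""


# ---------------------------------------------------------------------------
# attribute-value flat files
# ---------------------------------------------------------------------------

@dataclass
class AttributeValueRecord:
    """One ``//``-delimited block of an attribute-value flat file.

    ``attributes`` is a multimap: repeated attribute names keep every value in
    file order. Attribute names are upper-cased on ingest.
    """

    record_id: str
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def first(self, name: str, default: str = "") -> str:
        vals = self.attributes.get(name.upper())
        return vals[0] if vals else default

    def all(self, name: str) -> list[str]:
        return list(self.attributes.get(name.upper(), []))


def parse_attribute_value(path: str | Path) -> list[AttributeValueRecord]:
    """Parse a BioCyc-style attribute-value flat file.

    Records are separated by a line consisting of ``//``.  Attribute lines are
    ``NAME - value``; a line starting with ``/`` continues the previous value;
    lines starting with ``#`` are comments.  Blocks without a ``UNIQUE-ID``
    are skipped with a warning, as are attribute lines lacking the `` - ``
    separator.
    """
    path = Path(path)
    records: list[AttributeValueRecord] = []
    attrs: dict[str, list[str]] = {}
    last: tuple[str, int] | None = None  # (attr name, value index) for continuations

    def flush() -> None:
        nonlocal attrs, last
        if attrs:
            uid = attrs.get("UNIQUE-ID")
            if uid:
                records.append(AttributeValueRecord(uid[0], attrs))
            else:
                logger.warning("%s: block without UNIQUE-ID skipped", path.name)
        attrs = {}
        last = None

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.strip() == "//":
                flush()
                continue
            if line.startswith("/"):
                if last is None:
                    logger.warning("%s:%d: continuation with no attribute, skipped", path.name, lineno)
                    continue
                name, idx = last
                attrs[name][idx] = (attrs[name][idx] + " " + line[1:].strip()).strip()
                continue
            if not line.strip():
                continue
            if " - " not in line:
                logger.warning("%s:%d: malformed attribute line skipped: %r", path.name, lineno, line)
                continue
            name, value = line.split(" - ", 1)
            name = name.strip().upper()
            attrs.setdefault(name, []).append(value.strip())
            last = (name, len(attrs[name]) - 1)
    flush()
    return records


def serialize_attribute_value(records: Iterable[AttributeValueRecord]) -> str:
    """Normalized text form; re-parsing it reproduces the records."""
    chunks = []
    for rec in records:
        lines = []
        # UNIQUE-ID first so the block is self-identifying
        for name in ["UNIQUE-ID"] + [n for n in rec.attributes if n != "UNIQUE-ID"]:
            for value in rec.attributes.get(name, []):
                lines.append(f"{name} - {value}")
        chunks.append("\n".join(lines) + "\n//\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# relational pathway-database model
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    compound_id: str
    name: str = ""


@dataclass
class Reaction:
    reaction_id: str
    ec: str = ""
    substrates: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    reversible: bool = False
    pathway_ids: frozenset[str] = frozenset()
    #: explicit enzyme attribution; enzymes with a matching EC are added on query
    enzyme_ids: tuple[str, ...] = ()


@dataclass
class Enzyme:
    enzyme_id: str
    ec: str = ""
    name: str = ""


@dataclass
class Pathway:
    pathway_id: str
    name: str = ""
    reaction_order: tuple[str, ...] = ()


@dataclass
class PathwayDB:
    """In-memory relational view of one organism's pathway database.

    All mappings preserve insertion order. Compound identity is by id token
    after trimming, with case-insensitive resolution (first-seen spelling
    wins); names are never used for matching.
    """

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    enzymes: dict[str, Enzyme] = field(default_factory=dict)
    gene_enzyme: list[tuple[str, str]] = field(default_factory=list)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    # -- association helpers ------------------------------------------------

    def genes_of_enzyme(self, enzyme_id: str) -> tuple[str, ...]:
        return tuple(g for g, e in self.gene_enzyme if e == enzyme_id)

    def enzymes_of_gene(self, gene_id: str) -> tuple[str, ...]:
        return tuple(e for g, e in self.gene_enzyme if g == gene_id)

    def enzymes_of_reaction(self, reaction_id: str) -> tuple[str, ...]:
        """Enzymes attributed to a reaction: explicit links plus exact
        (non-empty) EC matches, in insertion order, deduplicated."""
        rxn = self.reactions[reaction_id]
        out: list[str] = [e for e in rxn.enzyme_ids if e in self.enzymes]
        if rxn.ec:
            out.extend(e.enzyme_id for e in self.enzymes.values()
                       if e.ec == rxn.ec and e.enzyme_id not in out)
        return tuple(out)

    def reactions_of_enzyme(self, enzyme_id: str) -> tuple[str, ...]:
        enz = self.enzymes[enzyme_id]
        out: list[str] = []
        for rxn in self.reactions.values():
            if enzyme_id in rxn.enzyme_ids or (enz.ec and rxn.ec == enz.ec):
                out.append(rxn.reaction_id)
        return tuple(out)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise if referential integrity or per-record invariants fail."""
        for rxn in self.reactions.values():
            for cid in rxn.substrates | rxn.products:
                if cid not in self.compounds:
                    raise PGDBFormatError(
                        f"reaction {rxn.reaction_id}: unresolved compound {cid!r}")
            if rxn.substrates & rxn.products:
                raise PGDBFormatError(
                    f"reaction {rxn.reaction_id}: substrates and products overlap")
        for gene, enzyme in self.gene_enzyme:
            if enzyme not in self.enzymes:
                raise PGDBFormatError(
                    f"gene_enzyme: unresolved enzyme {enzyme!r} (gene {gene!r})")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _split_multi(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    return [tok.strip() for tok in str(cell).split(";") if tok.strip()]


def _require_columns(df: pd.DataFrame, needed: Sequence[str], fname: str) -> None:
    for col in needed:
        if col not in df.columns:
            raise PGDBFormatError(f"{fname}: missing mandatory column {col!r}")


class _CompoundResolver:
    """Case-insensitive compound registry; auto-registers unknown tokens."""

    def __init__(self, db: PathwayDB) -> None:
        self.db = db
        self._by_fold = {cid.casefold(): cid for cid in db.compounds}
        self.auto_registered = 0

    def add(self, compound_id: str, name: str = "") -> None:
        cid = compound_id.strip()
        fold = cid.casefold()
        if fold not in self._by_fold:
            self.db.compounds[cid] = Compound(cid, name)
            self._by_fold[fold] = cid
        elif name and not self.db.compounds[self._by_fold[fold]].name:
            self.db.compounds[self._by_fold[fold]].name = name

    def resolve(self, token: str) -> str:
        tok = token.strip()
        fold = tok.casefold()
        if fold not in self._by_fold:
            self.db.compounds[tok] = Compound(tok, "")
            self._by_fold[fold] = tok
            self.auto_registered += 1
        return self._by_fold[fold]


def load_pathway_db(source: str | Path) -> PathwayDB:
    """Load a pathway database from a TSV bundle directory or a directory of
    BioCyc attribute-value flat files.

    Dangling references are repaired rather than fatal: unknown compounds are
    auto-registered with an empty name, gene links to unknown enzymes are
    dropped; both with logged counts.  The result satisfies
    :meth:`PathwayDB.validate`.
    """
    source = Path(source)
    if not source.is_dir():
        raise PGDBFormatError(f"{source}: pathway-database source must be a directory")
    if (source / "reactions.tsv").exists():
        return _load_tsv_bundle(source)
    return _load_attribute_value_dir(source)


def _load_tsv_bundle(root: Path) -> PathwayDB:
    db = PathwayDB()
    for fname in ("compounds.tsv", "reactions.tsv", "enzymes.tsv", "gene_enzyme.tsv"):
        if not (root / fname).exists():
            raise PGDBFormatError(f"{root / fname}: mandatory file missing")

    comp = pd.read_csv(root / "compounds.tsv", sep="\t", dtype=str, keep_default_na=False)
    _require_columns(comp, ["compound_id", "name"], "compounds.tsv")
    resolver = _CompoundResolver(db)
    for row in comp.itertuples(index=False):
        resolver.add(row.compound_id, row.name)

    enz = pd.read_csv(root / "enzymes.tsv", sep="\t", dtype=str, keep_default_na=False)
    _require_columns(enz, ["enzyme_id", "ec", "name"], "enzymes.tsv")
    for row in enz.itertuples(index=False):
        db.enzymes[row.enzyme_id.strip()] = Enzyme(row.enzyme_id.strip(), row.ec.strip(), row.name)

    rxn = pd.read_csv(root / "reactions.tsv", sep="\t", dtype=str, keep_default_na=False)
    _require_columns(rxn, ["reaction_id", "ec", "substrates", "products", "reversible"], "reactions.tsv")
    has_enzyme_col = "enzymes" in rxn.columns
    for row in rxn.itertuples(index=False):
        subs = frozenset(resolver.resolve(t) for t in _split_multi(row.substrates))
        prods = frozenset(resolver.resolve(t) for t in _split_multi(row.products))
        overlap = subs & prods
        if overlap:
            logger.warning("reaction %s: %d compound(s) on both sides dropped from products",
                           row.reaction_id, len(overlap))
            prods -= overlap
        enzyme_ids = tuple(_split_multi(row.enzymes)) if has_enzyme_col else ()
        unknown = [e for e in enzyme_ids if e not in db.enzymes]
        if unknown:
            logger.warning("reaction %s: %d unknown enzyme ref(s) dropped", row.reaction_id, len(unknown))
            enzyme_ids = tuple(e for e in enzyme_ids if e in db.enzymes)
        db.reactions[row.reaction_id.strip()] = Reaction(
            reaction_id=row.reaction_id.strip(),
            ec=row.ec.strip(),
            substrates=subs,
            products=prods,
            reversible=str(row.reversible).strip() in ("1", "true", "True"),
            pathway_ids=frozenset(_split_multi(getattr(row, "pathways", ""))),
            enzyme_ids=enzyme_ids,
        )

    ge = pd.read_csv(root / "gene_enzyme.tsv", sep="\t", dtype=str, keep_default_na=False)
    _require_columns(ge, ["gene_id", "enzyme_id"], "gene_enzyme.tsv")
    dropped = 0
    for row in ge.itertuples(index=False):
        if row.enzyme_id.strip() in db.enzymes:
            pair = (row.gene_id.strip(), row.enzyme_id.strip())
            if pair not in db.gene_enzyme:
                db.gene_enzyme.append(pair)
        else:
            dropped += 1
    if dropped:
        logger.warning("gene_enzyme.tsv: %d link(s) to unknown enzymes dropped", dropped)

    pw_path = root / "pathways.tsv"
    if pw_path.exists():
        pw = pd.read_csv(pw_path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(pw, ["pathway_id", "name"], "pathways.tsv")
        for row in pw.itertuples(index=False):
            order = tuple(_split_multi(getattr(row, "reaction_order", "")))
            db.pathways[row.pathway_id.strip()] = Pathway(row.pathway_id.strip(), row.name, order)

    if resolver.auto_registered:
        logger.warning("auto-registered %d unknown compound(s)", resolver.auto_registered)
    db.validate()
    return db


_AV_FILE_CANDIDATES = {
    "compounds": ("compounds.dat", "compounds.txt"),
    "reactions": ("reactions.dat", "reactions.txt"),
    "enzymes": ("proteins.dat", "enzymes.dat", "proteins.txt", "enzymes.txt"),
    "genes": ("genes.dat", "genes.txt"),
    "pathways": ("pathways.dat", "pathways.txt"),
}


def _find_av_file(root: Path, kind: str, mandatory: bool = True) -> Path | None:
    for cand in _AV_FILE_CANDIDATES[kind]:
        if (root / cand).exists():
            return root / cand
    if mandatory:
        raise PGDBFormatError(
            f"{root}: no {kind} flat file (looked for {', '.join(_AV_FILE_CANDIDATES[kind])})")
    return None


def _load_attribute_value_dir(root: Path) -> PathwayDB:
    db = PathwayDB()
    resolver = _CompoundResolver(db)

    for rec in parse_attribute_value(_find_av_file(root, "compounds")):
        resolver.add(rec.record_id, rec.first("COMMON-NAME"))

    catalyzes: dict[str, list[str]] = {}  # reaction -> enzyme ids
    for rec in parse_attribute_value(_find_av_file(root, "enzymes")):
        db.enzymes[rec.record_id] = Enzyme(rec.record_id, rec.first("EC-NUMBER"), rec.first("COMMON-NAME"))
        for rid in rec.all("CATALYZES"):
            catalyzes.setdefault(rid, []).append(rec.record_id)

    for rec in parse_attribute_value(_find_av_file(root, "reactions")):
        subs = frozenset(resolver.resolve(t) for t in rec.all("LEFT"))
        prods = frozenset(resolver.resolve(t) for t in rec.all("RIGHT")) - subs
        direction = rec.first("REACTION-DIRECTION", "LEFT-TO-RIGHT")
        db.reactions[rec.record_id] = Reaction(
            reaction_id=rec.record_id,
            ec=rec.first("EC-NUMBER"),
            substrates=subs,
            products=prods,
            reversible="REVERSIBLE" in direction.upper(),
            pathway_ids=frozenset(rec.all("IN-PATHWAY")),
            enzyme_ids=tuple(e for e in catalyzes.get(rec.record_id, []) if e in db.enzymes),
        )

    dropped = 0
    for rec in parse_attribute_value(_find_av_file(root, "genes")):
        for enzyme_id in rec.all("PRODUCT"):
            if enzyme_id in db.enzymes:
                pair = (rec.record_id, enzyme_id)
                if pair not in db.gene_enzyme:
                    db.gene_enzyme.append(pair)
            else:
                dropped += 1
    if dropped:
        logger.warning("genes flat file: %d product link(s) to unknown enzymes dropped", dropped)

    pw_path = _find_av_file(root, "pathways", mandatory=False)
    if pw_path is not None:
        for rec in parse_attribute_value(pw_path):
            order = tuple(rec.all("REACTION-LIST"))
            db.pathways[rec.record_id] = Pathway(rec.record_id, rec.first("COMMON-NAME"), order)

    if resolver.auto_registered:
        logger.warning("auto-registered %d unknown compound(s)", resolver.auto_registered)
    db.validate()
    return db


def export_tsv_bundle(db: PathwayDB, out_dir: str | Path) -> None:
    """Write a PathwayDB as the canonical TSV bundle (inverse of loading)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(c.compound_id, c.name) for c in db.compounds.values()],
        columns=["compound_id", "name"],
    ).to_csv(out / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (
                r.reaction_id,
                r.ec,
                ";".join(sorted(r.substrates)),
                ";".join(sorted(r.products)),
                int(r.reversible),
                ";".join(sorted(r.pathway_ids)),
                ";".join(r.enzyme_ids),
            )
            for r in db.reactions.values()
        ],
        columns=["reaction_id", "ec", "substrates", "products", "reversible", "pathways", "enzymes"],
    ).to_csv(out / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(e.enzyme_id, e.ec, e.name) for e in db.enzymes.values()],
        columns=["enzyme_id", "ec", "name"],
    ).to_csv(out / "enzymes.tsv", sep="\t", index=False)
    pd.DataFrame(db.gene_enzyme, columns=["gene_id", "enzyme_id"]).to_csv(
        out / "gene_enzyme.tsv", sep="\t", index=False)
    if db.pathways:
        pd.DataFrame(
            [(p.pathway_id, p.name, ";".join(p.reaction_order)) for p in db.pathways.values()],
            columns=["pathway_id", "name", "reaction_order"],
        ).to_csv(out / "pathways.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# DEG tables, PPI lists, SIF files
# ---------------------------------------------------------------------------

def load_deg_table(path: str | Path) -> pd.DataFrame:
    """Load a DEG table (columns gene_id, contrast, log2fc, fdr).

    Rows with unparseable or missing statistics are dropped with a warning.
    Duplicate (gene_id, contrast) rows raise a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contrast": str})
    _require_columns(df, list(DEG_COLUMNS), Path(path).name)
    df = df.loc[:, list(DEG_COLUMNS)].copy()
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    df["fdr"] = pd.to_numeric(df["fdr"], errors="coerce")
    bad = df["log2fc"].isna() | df["fdr"].isna()
    if bad.any():
        logger.warning("%s: %d row(s) with missing statistics skipped", path, int(bad.sum()))
        df = df.loc[~bad]
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise PGDBFormatError(f"{path}: fdr outside [0, 1]")
    if df.duplicated(["gene_id", "contrast"]).any():
        raise PGDBFormatError(f"{path}: duplicate (gene_id, contrast) rows")
    return df.reset_index(drop=True)


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(DEG_COLUMNS)].to_csv(path, sep="\t", index=False)


@dataclass
class PPIEdgeList:
    """Undirected, deduplicated protein-protein interaction pairs."""

    pairs: set[frozenset[str]] = field(default_factory=set)

    def add(self, a: str, b: str) -> None:
        a, b = a.strip(), b.strip()
        if a and b and a != b:
            self.pairs.add(frozenset((a, b)))

    def neighbors(self, protein: str) -> set[str]:
        out: set[str] = set()
        for pair in self.pairs:
            if protein in pair:
                out.update(pair - {protein})
        return out

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self.pairs


def load_ppi(path: str | Path) -> PPIEdgeList:
    """Read a two-column whitespace-delimited interaction list.

    Self-pairs are rejected with a warning; (a,b) and (b,a) collapse to one.
    """
    ppi = PPIEdgeList()
    rejected = 0
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 2:
                raise PGDBFormatError(f"{path}:{lineno}: expected 2 ids, got {len(toks)}")
            if toks[0] == toks[1]:
                rejected += 1
                continue
            ppi.add(*toks)
    if rejected:
        logger.warning("%s: %d self-pair(s) rejected", path, rejected)
    return ppi


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (source, relation, target) triples in Cytoscape SIF format."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for src, rel, dst in edges:
            fh.write(f"{src}\t{rel}\t{dst}\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read SIF triples; a line with other than 3 tokens is a format error."""
    out: list[tuple[str, str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 3:
                raise PGDBFormatError(f"{path}:{lineno}: SIF line has {len(toks)} tokens, expected 3")
            out.append((toks[0], toks[1], toks[2]))
    return out
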