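"""Synthetic pathway databases, planted-route benchmarks, and packaged
worked-example fixtures.

The random generator builds small but structurally realistic pathway
databases (reactions drawing 1-3 substrates/products from a compound pool,
optional currency-metabolite attachment, enzymes and genes wired on) that
are bit-for-bit reproducible under a seed. ``plant_linear_route`` appends a
linear reaction chain with known DEG coverage so the whole pipeline can be
checked against a planted truth.

The ``paper_fixture`` catalogue packages small hand-transcribed pathway
fragments from published pollination expression studies in *Arabidopsis*
and maize (ethanol degradation II, a TCA-cycle variation, glycolysis IV,
kaempferol and dTDP-L-rhamnose biosynthesis, phosphatidic-acid production,
and the GABA shunt), each with its DEG gene lists, so every pipeline stage
runs against a known expected outcome with no download. The lily
glycolysis/TCA superpathway entry is a synthetic stand-in: only its step
count is documented, so its enzymes and compounds are generated labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .build import default_currency_set
from .pgdb_io import Compound, Enzyme, PathwayDB, Pathway, Reaction

__all__ = ["FixtureSpec", "FixtureSpecError", "PaperFixture", "PlantedRoute",
           "make_random_pgdb", "make_random_deg_table", "plant_linear_route",
           "paper_fixture", "PAPER_FIXTURE_NAMES"]


class FixtureSpecError(ValueError):
    """Infeasible generator parameters."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one randomly generated pathway-database fixture."""

    name: str = "random"
    seed: int = 0
    n_compounds: int = 30
    n_reactions: int = 20
    n_enzymes: int = 20
    n_genes: int = 40
    p_currency_usage: float = 0.2
    deg_fraction: float = 0.3

    def __post_init__(self) -> None:
        for attr in ("n_compounds", "n_reactions", "n_enzymes", "n_genes"):
            if getattr(self, attr) < 0:
                raise FixtureSpecError(f"{attr} must be >= 0")
        for attr in ("p_currency_usage", "deg_fraction"):
            if not 0 <= getattr(self, attr) <= 1:
                raise FixtureSpecError(f"{attr} must be in [0, 1]")
        if self.n_reactions and self.n_enzymes > 3 * self.n_reactions:
            raise FixtureSpecError("more enzymes than reactions can carry (max 3 per reaction)")
        if self.n_enzymes and not self.n_reactions:
            raise FixtureSpecError("enzymes require at least one reaction")


def make_random_pgdb(spec: FixtureSpec) -> PathwayDB:
    """Generate a random pathway database, deterministic under ``spec.seed``.

    Each reaction draws 1-3 substrates and 1-3 products (disjoint) from the
    compound pool; reactions after the first reuse a product of an earlier
    reaction as a substrate, so the reaction set is connected by
    construction. Currency compounds are attached to either side with
    probability ``p_currency_usage``. Enzymes are attributed round-robin
    (at most 3 per reaction) and genes round-robin over enzymes.
    """
    rng = np.random.default_rng(spec.seed)
    db = PathwayDB()
    pool = [f"C{i:04d}" for i in range(1, spec.n_compounds + 1)]
    for cid in pool:
        db.compounds[cid] = Compound(cid, "")
    currency_tokens = sorted(default_currency_set())
    for tok in currency_tokens:
        db.compounds.setdefault(tok, Compound(tok, ""))

    prior_products: list[str] = []
    for i in range(1, spec.n_reactions + 1):
        rid = f"R{i:04d}"
        n_sub = int(rng.integers(1, 4))
        n_prod = int(rng.integers(1, 4))
        picks = list(rng.choice(pool, size=min(n_sub + n_prod, len(pool)), replace=False)) \
            if pool else []
        subs = set(picks[:n_sub])
        prods = set(picks[n_sub:n_sub + n_prod])
        if prior_products and subs:
            reuse = str(rng.choice(prior_products))
            if reuse not in prods:
                subs = (subs - {min(subs)}) | {reuse}
        if rng.random() < spec.p_currency_usage:
            subs.add(str(rng.choice(currency_tokens)))
        if rng.random() < spec.p_currency_usage:
            tok = str(rng.choice(currency_tokens))
            if tok not in subs:
                prods.add(tok)
        prods -= subs
        if not prods and pool:
            extra = str(rng.choice([c for c in pool if c not in subs] or pool))
            prods = {extra} - subs
        ec = f"{rng.integers(1, 7)}.{rng.integers(1, 5)}.{rng.integers(1, 5)}.{rng.integers(1, 30)}"
        db.reactions[rid] = Reaction(rid, ec, frozenset(subs), frozenset(prods),
                                     reversible=bool(rng.random() < 0.2))
        prior_products.extend(sorted(prods))

    rxn_ids = list(db.reactions)
    for j in range(1, spec.n_enzymes + 1):
        eid = f"E{j:04d}"
        host = rxn_ids[(j - 1) % len(rxn_ids)]
        db.enzymes[eid] = Enzyme(eid, db.reactions[host].ec, "")
        db.reactions[host] = Reaction(
            **{**db.reactions[host].__dict__,
               "enzyme_ids": db.reactions[host].enzyme_ids + (eid,)})

    enz_ids = list(db.enzymes)
    for k in range(1, spec.n_genes + 1):
        if not enz_ids:
            break
        db.gene_enzyme.append((f"G{k:04d}", enz_ids[(k - 1) % len(enz_ids)]))

    db.validate()
    return db


def make_random_deg_table(spec: FixtureSpec, db: PathwayDB) -> pd.DataFrame:
    """DEG table over the database's genes: a ``deg_fraction`` of genes get
    qualifying statistics (|log2fc| >= 1, fdr <= 1e-12); filler rows draw
    log2fc from (-0.5, 0.5) and fdr from (0.1, 1) so they can never pass the
    default thresholds."""
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted({g for g, _ in db.gene_enzyme})
    rows = []
    for gene in genes:
        if rng.random() < spec.deg_fraction:
            lfc = float(rng.uniform(1.0, 4.0)) * (1 if rng.random() < 0.5 else -1)
            fdr = float(rng.uniform(0, 1e-12))
        else:
            lfc = float(rng.uniform(-0.5, 0.5))
            fdr = float(rng.uniform(0.1, 1.0))
        rows.append((gene, spec.name, lfc, fdr))
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "fdr"])


@dataclass
class PlantedRoute:
    """Ground truth of a planted linear chain."""

    reaction_ids: tuple[str, ...]
    covered_steps: frozenset[int]
    #: maximal contiguous runs of covered steps, as reaction-id tuples
    runs: tuple[tuple[str, ...], ...]

    @property
    def longest_run(self) -> int:
        return max((len(r) for r in self.runs), default=0)


def plant_linear_route(db: PathwayDB, length: int, deg_coverage: set[int] | None = None,
                       seed: int = 0) -> tuple[PathwayDB, pd.DataFrame, PlantedRoute]:
    """Append a linear chain of ``length`` reactions to ``db`` (in place).

    Steps are linked by fresh non-currency compounds; each step gets one new
    enzyme and gene. ``deg_coverage`` holds the 0-based step indices whose
    gene receives qualifying DE statistics (log2fc 2.0, fdr 1e-12); the
    remaining genes get non-significant filler drawn under ``seed``. Returns
    (db, DEG table, planted truth); the truth's maximal covered runs are what
    a correct pipeline must recover.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    coverage = set(range(length)) if deg_coverage is None else set(deg_coverage)
    rng = np.random.default_rng(seed)
    tag = f"PL{len(db.reactions):03d}"
    compounds = [f"{tag}-C{i:03d}" for i in range(length + 1)]
    for cid in compounds:
        db.compounds[cid] = Compound(cid, "")
    rows = []
    rids = []
    for i in range(length):
        rid = f"{tag}-R{i + 1:03d}"
        eid = f"{tag}-E{i + 1:03d}"
        gid = f"{tag}-G{i + 1:03d}"
        db.enzymes[eid] = Enzyme(eid, "", f"planted step {i + 1}")
        db.reactions[rid] = Reaction(rid, "", frozenset({compounds[i]}),
                                     frozenset({compounds[i + 1]}), enzyme_ids=(eid,))
        db.gene_enzyme.append((gid, eid))
        rids.append(rid)
        if i in coverage:
            rows.append((gid, "planted", 2.0, 1e-12))
        else:
            rows.append((gid, "planted", float(rng.uniform(-0.5, 0.5)),
                         float(rng.uniform(0.1, 1.0))))
    db.pathways[f"{tag}-PWY"] = Pathway(f"{tag}-PWY", "planted linear route", tuple(rids))

    runs: list[tuple[str, ...]] = []
    current: list[str] = []
    for i, rid in enumerate(rids):
        if i in coverage:
            current.append(rid)
        elif current:
            runs.append(tuple(current))
            current = []
    if current:
        runs.append(tuple(current))
    truth = PlantedRoute(tuple(rids), frozenset(coverage & set(range(length))), tuple(runs))
    deg = pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "fdr"])
    db.validate()
    return db, deg, truth


# ---------------------------------------------------------------------------
# packaged worked-example fixtures
# ---------------------------------------------------------------------------

@dataclass
class PaperFixture:
    """A transcribed pathway fragment with its DEG table and expected
    pipeline outcomes (chain length, longest route length, per-EC DEG gene
    counts)."""

    name: str
    db: PathwayDB
    deg_table: pd.DataFrame
    pathway_id: str
    expected: dict = field(default_factory=dict)
    linear: bool = True
    notes: str = ""


def _assemble(name: str, pathway_id: str, pathway_name: str,
              steps: list[dict], declared_order: bool = True,
              contrast: str = "pollination") -> tuple[PathwayDB, pd.DataFrame]:
    """Build a PathwayDB + DEG table from per-step descriptions.

    Each step: reaction_id, ec, enzyme (entity id), enzyme_name, genes,
    substrates, products. Steps sharing an enzyme id share the entity.
    """
    db = PathwayDB()
    rows = []
    seen_genes: set[str] = set()
    for step in steps:
        for cid in list(step["substrates"]) + list(step["products"]):
            db.compounds.setdefault(cid, Compound(cid, ""))
        eid = step["enzyme"]
        if eid not in db.enzymes:
            db.enzymes[eid] = Enzyme(eid, step["ec"], step.get("enzyme_name", ""))
        db.reactions[step["reaction_id"]] = Reaction(
            reaction_id=step["reaction_id"],
            ec=step["ec"],
            substrates=frozenset(step["substrates"]),
            products=frozenset(step["products"]),
            pathway_ids=frozenset({pathway_id}),
            enzyme_ids=(eid,),
        )
        for gene in step["genes"]:
            if (gene, eid) not in db.gene_enzyme:
                db.gene_enzyme.append((gene, eid))
            if gene not in seen_genes:
                seen_genes.add(gene)
                rows.append((gene, contrast, 2.0, 1e-12))
    order = tuple(s["reaction_id"] for s in steps) if declared_order else ()
    db.pathways[pathway_id] = Pathway(pathway_id, pathway_name, order)
    db.validate()
    deg = pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "fdr"])
    return db, deg


def _fig5() -> PaperFixture:
    steps = [
        dict(reaction_id="ETOH-DEG-RXN-1", ec="1.1.1.1", enzyme="ALCOHOL-DEHYDROGENASE",
             enzyme_name="alcohol dehydrogenase", genes=["AT5G63620"],
             substrates=["ethanol"], products=["acetaldehyde"]),
        dict(reaction_id="ETOH-DEG-RXN-2", ec="1.2.1.3", enzyme="ALDEHYDE-DEHYDROGENASE",
             enzyme_name="aldehyde dehydrogenase", genes=["AT1G54100"],
             substrates=["acetaldehyde"], products=["acetate"]),
        dict(reaction_id="ETOH-DEG-RXN-3", ec="6.2.1.1", enzyme="ACETYL-COA-SYNTHETASE",
             enzyme_name="acetyl-CoA synthetase", genes=["AT5G36880"],
             substrates=["acetate"], products=["acetyl-CoA"]),
    ]
    db, deg = _assemble("fig5", "ETHANOL-DEG-II-PWY", "ethanol degradation II", steps,
                        contrast="SIV_PT_vs_4HPT")
    return PaperFixture(
        "fig5_ethanol_degradation_II", db, deg, "ETHANOL-DEG-II-PWY",
        expected=dict(chain_length=3, route_length=3,
                      genes_per_ec={"1.1.1.1": 1, "1.2.1.3": 1, "6.2.1.1": 1},
                      linking_compounds=("acetaldehyde", "acetate")),
        notes="Arabidopsis pollen-tube ethanol degradation II: "
              "ethanol -> acetaldehyde -> acetate -> acetyl-CoA.",
    )


def _fig6() -> PaperFixture:
    steps = [
        dict(reaction_id="TCA-VAR-RXN-1", ec="1.1.1.41", enzyme="ISOCITRATE-DH-NAD",
             enzyme_name="isocitrate dehydrogenase (NAD+)", genes=["AT2G17130"],
             substrates=["D-threo-isocitrate"], products=["2-oxoglutarate"]),
        dict(reaction_id="TCA-VAR-RXN-2", ec="1.2.4.2", enzyme="OXOGLUTARATE-DH-E1",
             enzyme_name="2-oxoglutarate dehydrogenase E1", genes=["AT5G65750", "AT3G55410"],
             substrates=["2-oxoglutarate"], products=["succinyl-CoA"]),
        dict(reaction_id="TCA-VAR-RXN-3", ec="6.2.1.5", enzyme="SUCCINYL-COA-SYNTHETASE",
             enzyme_name="succinyl-CoA synthetase", genes=["AT5G08300"],
             substrates=["succinyl-CoA"], products=["succinate"]),
        dict(reaction_id="TCA-VAR-RXN-4", ec="1.3.5.1", enzyme="SUCCINATE-DH-FLAVO",
             enzyme_name="succinate dehydrogenase (ubiquinone) flavoprotein subunit",
             genes=["AT5G66760"],
             substrates=["succinate"], products=["fumarate"]),
    ]
    db, deg = _assemble("fig6", "TCA-VARIATION-PWY", "TCA cycle variation", steps,
                        contrast="SIV_PT_vs_4HPT")
    return PaperFixture(
        "fig6_tca_variation", db, deg, "TCA-VARIATION-PWY",
        expected=dict(chain_length=4, route_length=4,
                      genes_per_ec={"1.1.1.41": 1, "1.2.4.2": 2, "6.2.1.5": 1, "1.3.5.1": 1}),
        notes="Pollen-tube TCA-cycle variation: isocitrate -> 2-oxoglutarate -> "
              "succinyl-CoA -> succinate -> fumarate.",
    )


def _fig7() -> PaperFixture:
    steps = [
        dict(reaction_id="GLYC-IV-RXN-1", ec="2.7.1.90", enzyme="F6P-1-PHOSPHOTRANSFERASE",
             enzyme_name="fructose-6-phosphate 1-phosphotransferase",
             genes=["GRMZM2G042502", "GRMZM2G059151", "GRMZM2G123371", "GRMZM2G450163",
                    "AT1G20950", "AT4G04040"],
             substrates=["D-fructose-6-phosphate"], products=["fructose-1,6-bisphosphate"]),
        # no differentially expressed gene encodes aldolase in either species:
        # the enzyme is present but carries no gene links
        dict(reaction_id="GLYC-IV-RXN-2", ec="4.1.2.13", enzyme="FBP-ALDOLASE",
             enzyme_name="fructose-bisphosphate aldolase", genes=[],
             substrates=["fructose-1,6-bisphosphate"], products=["D-glyceraldehyde 3-phosphate"]),
        dict(reaction_id="GLYC-IV-RXN-3", ec="1.2.1.12", enzyme="GAPDH",
             enzyme_name="glyceraldehyde-3-phosphate dehydrogenase",
             genes=["GRMZM2G046804", "GRMZM2G051004", "GRMZM2G071630", "GRMZM2G104632",
                    "GRMZM2G176307", "AT1G16300", "AT1G79530"],
             substrates=["D-glyceraldehyde 3-phosphate"], products=["1,3-bisphospho-D-glycerate"]),
        dict(reaction_id="GLYC-IV-RXN-4", ec="2.7.2.3", enzyme="PHOSPHOGLYCERATE-KINASE",
             enzyme_name="phosphoglycerate kinase",
             genes=["GRMZM2G083016", "GRMZM2G089136"],
             substrates=["1,3-bisphospho-D-glycerate"], products=["3-phospho-D-glycerate"]),
        dict(reaction_id="GLYC-IV-RXN-5", ec="5.4.2.1", enzyme="PHOSPHOGLYCERATE-MUTASE",
             enzyme_name="2,3-bisphosphoglycerate-dependent phosphoglycerate mutase",
             genes=["GRMZM2G021605", "AT1G09780"],
             substrates=["3-phospho-D-glycerate"], products=["2-phospho-D-glycerate"]),
        dict(reaction_id="GLYC-IV-RXN-6", ec="4.2.1.11", enzyme="ENOLASE",
             enzyme_name="enolase", genes=["AT1G74030"],
             substrates=["2-phospho-D-glycerate"], products=["phosphoenolpyruvate"]),
        dict(reaction_id="GLYC-IV-RXN-7", ec="2.7.1.40", enzyme="PYRUVATE-KINASE",
             enzyme_name="pyruvate kinase",
             genes=["GRMZM2G004534", "GRMZM2G033526", "GRMZM2G066290", "GRMZM2G124593",
                    "GRMZM2G144730", "GRMZM2G177947"],
             substrates=["phosphoenolpyruvate"], products=["pyruvate"]),
    ]
    db, deg = _assemble("fig7", "GLYCOLYSIS-IV-PWY", "glycolysis IV (plant cytosol)", steps,
                        contrast="stigma_pollination")
    return PaperFixture(
        "fig7_glycolysis_IV", db, deg, "GLYCOLYSIS-IV-PWY",
        expected=dict(chain_length=7, route_length=5,
                      genes_per_ec={"2.7.1.90": 6, "4.1.2.13": 0, "1.2.1.12": 7, "2.7.2.3": 2,
                                    "5.4.2.1": 2, "4.2.1.11": 1, "2.7.1.40": 6}),
        notes="Stigma glycolysis IV: the aldolase step (EC 4.1.2.13) has no DEG "
              "in either species, so the longest DEG-covered route spans steps 3-7.",
    )


def _fig8() -> PaperFixture:
    # intermediates are the standard phenylpropanoid/flavonoid pathway
    # metabolites; the source presents them graphically
    steps = [
        dict(reaction_id="KAEMPF-RXN-1", ec="4.3.1.24", enzyme="PAL",
             enzyme_name="phenylalanine ammonia-lyase",
             genes=["GRMZM2G029048", "GRMZM2G074604", "GRMZM2G081582", "GRMZM2G118345",
                    "GRMZM2G160541", "GRMZM2G170692", "GRMZM2G441347", "AT2G37040"],
             substrates=["L-phenylalanine"], products=["trans-cinnamate"]),
        dict(reaction_id="KAEMPF-RXN-2", ec="1.14.13.11", enzyme="C4H",
             enzyme_name="trans-cinnamate 4-monooxygenase",
             genes=["GRMZM2G010468", "GRMZM2G139874", "GRMZM2G147245", "AT2G30490"],
             substrates=["trans-cinnamate"], products=["4-coumarate"]),
        dict(reaction_id="KAEMPF-RXN-3", ec="6.2.1.12", enzyme="4CL",
             enzyme_name="4-coumarate:CoA ligase",
             genes=["GRMZM2G054013", "GRMZM2G055320", "GRMZM2G075333", "GRMZM2G122787",
                    "GRMZM2G174574", "AT1G65060", "AT1G21540"],
             substrates=["4-coumarate"], products=["4-coumaroyl-CoA"]),
        dict(reaction_id="KAEMPF-RXN-4", ec="2.3.1.74", enzyme="CHS",
             enzyme_name="chalcone synthase",
             genes=["AC148152.3", "GRMZM2G009348", "GRMZM2G151227", "AT5G13930"],
             substrates=["4-coumaroyl-CoA"], products=["naringenin chalcone"]),
        dict(reaction_id="KAEMPF-RXN-5", ec="5.5.1.6", enzyme="CHI",
             enzyme_name="naringenin chalcone isomerase",
             genes=["GRMZM2G119186", "GRMZM2G155329", "AT3G55120"],
             substrates=["naringenin chalcone"], products=["naringenin"]),
        dict(reaction_id="KAEMPF-RXN-6", ec="1.14.11.9", enzyme="F3H",
             enzyme_name="flavanone 3-dioxygenase",
             genes=["GRMZM2G060940", "GRMZM2G062396", "GRMZM2G099467", "AT3G51240",
                    "AT3G55970", "AT3G60290", "AT4G22870", "AT5G05600", "AT5G08640",
                    "AT5G24530"],
             substrates=["naringenin"], products=["dihydrokaempferol"]),
        dict(reaction_id="KAEMPF-RXN-7", ec="1.14.11.23", enzyme="FLS",
             enzyme_name="flavonol synthase",
             genes=["GRMZM2G099467", "AT3G60290", "AT4G22880", "AT5G08640"],
             substrates=["dihydrokaempferol"], products=["kaempferol"]),
    ]
    db, deg = _assemble("fig8", "KAEMPFEROL-PWY", "kaempferol biosynthesis", steps,
                        contrast="stigma_pollination")
    return PaperFixture(
        "fig8_kaempferol", db, deg, "KAEMPFEROL-PWY",
        expected=dict(chain_length=7, route_length=7,
                      genes_per_ec={"4.3.1.24": 8, "1.14.13.11": 4, "6.2.1.12": 7,
                                    "2.3.1.74": 4, "5.5.1.6": 3, "1.14.11.9": 10,
                                    "1.14.11.23": 4}),
        notes="Kaempferol biosynthesis from L-phenylalanine in stigmas; every "
              "step DEG-covered in at least one species.",
    )


def _fig9() -> PaperFixture:
    # steps 3 and 4 are both catalyzed by flavonol-3-O-rhamnosyltransferase
    # (one enzyme entity, partial EC 2.4.1.-); the NRS/ER step-2 enzymes carry
    # no EC number, so EC-keyed overlap analysis excludes them by design
    steps = [
        dict(reaction_id="RHAM-RXN-1", ec="4.2.1.46", enzyme="DTDP-GLUCOSE-DEHYDRATASE",
             enzyme_name="dTDP-glucose 4,6-dehydratase",
             genes=["GRMZM2G031311", "GRMZM2G166767", "AT1G78570", "AT3G14790"],
             substrates=["dTDP-alpha-D-glucose"],
             products=["dTDP-4-dehydro-6-deoxy-alpha-D-glucose"]),
        dict(reaction_id="RHAM-RXN-2", ec="", enzyme="NRS-ER",
             enzyme_name="NRS/ER",
             genes=["GRMZM2G166767", "GRMZM2G031311", "AT1G63000"],
             substrates=["dTDP-4-dehydro-6-deoxy-alpha-D-glucose"],
             products=["dTDP-alpha-L-rhamnose"]),
        dict(reaction_id="RHAM-RXN-3", ec="2.4.1.-", enzyme="F3-RHAMNOSYLTRANSFERASE",
             enzyme_name="flavonol-3-O-rhamnosyltransferase",
             genes=["AT1G06000", "AT1G22370", "AT1G30530", "AT2G30140", "AT3G46660",
                    "AT5G12890", "AT5G17050"],
             substrates=["kaempferol", "dTDP-alpha-L-rhamnose"],
             products=["kaempferol-3-rhamnoside"]),
        dict(reaction_id="RHAM-RXN-4", ec="2.4.1.-", enzyme="F3-RHAMNOSYLTRANSFERASE",
             enzyme_name="flavonol-3-O-rhamnosyltransferase", genes=[],
             substrates=["kaempferol-3-rhamnoside", "dTDP-alpha-L-rhamnose"],
             products=["kaempferol-3-rhamnoside-7-rhamnoside"]),
    ]
    db, deg = _assemble("fig9", "RHAMNOSE-KAEMPF-PWY",
                        "dTDP-L-rhamnose and kaempferol glucoside biosynthesis", steps,
                        contrast="stigma_pollination")
    return PaperFixture(
        "fig9_rhamnose_kaempferol_glucoside", db, deg, "RHAMNOSE-KAEMPF-PWY",
        expected=dict(chain_length=4, route_length=4,
                      genes_per_ec={"4.2.1.46": 4, "2.4.1.-": 7}),
        notes="Cooperation of kaempferol and dTDP-alpha-L-rhamnose; the step-2 "
              "NRS/ER enzymes have no EC assignment.",
    )


def _fig10() -> PaperFixture:
    steps = [
        dict(reaction_id="PA-RXN-1", ec="2.7.1.67", enzyme="PI4K",
             enzyme_name="phosphoinositide 4-kinase",
             genes=["GRMZM2G114162", "GRMZM2G137558", "GRMZM2G408359", "AT3G56600"],
             substrates=["L-1-phosphatidyl-inositol"],
             products=["1-phosphatidyl-1D-myo-inositol 4-phosphate"]),
        dict(reaction_id="PA-RXN-2", ec="2.7.1.68", enzyme="PIP5K",
             enzyme_name="phosphoinositide phosphate 5-kinase",
             genes=["GRMZM2G062045", "GRMZM2G076392", "GRMZM2G116010", "GRMZM2G157147",
                    "GRMZM5G831486", "AT1G01460"],
             substrates=["1-phosphatidyl-1D-myo-inositol 4-phosphate"],
             products=["PtdIns(4,5)P2"]),
        dict(reaction_id="PA-RXN-3", ec="3.1.4.11", enzyme="PLC",
             enzyme_name="phospholipase C", genes=["GRMZM2G137435"],
             substrates=["PtdIns(4,5)P2"],
             products=["1,2-diacylglycerol", "Ins(1,4,5)P3"]),
        dict(reaction_id="PA-RXN-4", ec="2.3.1.51", enzyme="LPAAT",
             enzyme_name="1-acylglycerol-3-phosphate O-acyltransferase",
             genes=["GRMZM2G014981", "GRMZM2G037104", "GRMZM2G135027", "GRMZM2G165681",
                    "GRMZM2G481755", "AT2G38110"],
             substrates=["1-acyl-sn-glycerol-3-phosphate"],
             products=["1,2-diacyl-sn-glycerol-3-phosphate"]),
        dict(reaction_id="PA-RXN-5", ec="3.1.4.4", enzyme="PLD",
             enzyme_name="phospholipase D",
             genes=["GRMZM2G061969", "GRMZM2G108912", "GRMZM2G133943", "GRMZM2G140811",
                    "GRMZM2G145944", "GRMZM2G179792", "GRMZM2G312438", "GRMZM2G442551"],
             substrates=["phosphatidylcholine"],
             products=["1,2-diacyl-sn-glycerol-3-phosphate"]),
        dict(reaction_id="PA-RXN-6", ec="3.1.3.4", enzyme="PAP",
             enzyme_name="phosphatidate phosphatase",
             genes=["GRMZM2G050658", "AT3G18220"],
             substrates=["1,2-diacyl-sn-glycerol-3-phosphate"],
             products=["1,2-diacylglycerol"]),
        dict(reaction_id="PA-RXN-7", ec="2.3.1.20", enzyme="DGAT",
             enzyme_name="diacylglycerol O-acyltransferase",
             genes=["GRMZM2G130749", "AT5G37300"],
             substrates=["1,2-diacylglycerol"], products=["triacylglycerol"]),
        dict(reaction_id="PA-RXN-8", ec="3.1.1.3", enzyme="TAG-LIPASE",
             enzyme_name="triacylglycerol lipase",
             genes=["GRMZM2G035421", "GRMZM2G064594", "GRMZM2G080940", "GRMZM2G087612",
                    "AT4G10955", "AT5G14180"],
             substrates=["triacylglycerol"], products=["DAG"]),
        dict(reaction_id="PA-RXN-9", ec="2.7.1.107", enzyme="DGK",
             enzyme_name="diacylglycerol kinase",
             genes=["AT5G63770", "AT4G30340"],
             substrates=["DAG"], products=["PA"]),
    ]
    db, deg = _assemble("fig10", "PA-BIOSYNTHESIS-PWY", "phosphatidic acid biosynthesis",
                        steps, declared_order=False, contrast="stigma_pollination")
    return PaperFixture(
        "fig10_pa_biosynthesis", db, deg, "PA-BIOSYNTHESIS-PWY",
        expected=dict(n_steps=9, route_length=6),
        linear=False,
        notes="Phosphatidic-acid production is a branched network (PLC- and "
              "PLD-initiated branches converging on diacylglycerol), so the "
              "pathway yields a chain cover rather than a single chain.",
    )


def _fig11() -> PaperFixture:
    # step 3 follows the source text verbatim ("succinate semialdehyde to
    # GABA"), which is inverted relative to the canonical GABA shunt; the
    # discrepancy is preserved, not corrected
    steps = [
        dict(reaction_id="GABA-RXN-1", ec="4.1.1.15", enzyme="GLUTAMATE-DECARBOXYLASE",
             enzyme_name="glutamate decarboxylase",
             genes=["GRMZM2G017110", "GRMZM2G098875", "AT2G02000", "AT2G02010"],
             substrates=["L-glutamate"], products=["4-aminobutyrate"]),
        dict(reaction_id="GABA-RXN-2", ec="2.6.1.-", enzyme="TYROSINE-AMINOTRANSFERASE",
             enzyme_name="tyrosine aminotransferase",
             genes=["AT1G50110", "AT3G22200"],
             substrates=["4-aminobutyrate"], products=["succinate semialdehyde"]),
        dict(reaction_id="GABA-RXN-3", ec="1.2.1.-", enzyme="HYDROXYBUTYRATE-DH",
             enzyme_name="3-hydroxybutyrate dehydrogenase",
             genes=["AT4G33790", "AT5G22500"],
             substrates=["succinate semialdehyde"], products=["GABA"]),
    ]
    db, deg = _assemble("fig11", "GLUTAMATE-DEG-IV-PWY", "glutamate degradation IV", steps,
                        contrast="stigma_pollination")
    return PaperFixture(
        "fig11_gaba_shunt", db, deg, "GLUTAMATE-DEG-IV-PWY",
        expected=dict(chain_length=3, route_length=3,
                      genes_per_ec={"4.1.1.15": 4, "2.6.1.-": 2, "1.2.1.-": 2}),
        notes="Glutamate degradation IV (GABA shunt) in stigmas; links are "
              "4-aminobutyrate and succinate semialdehyde, so the glutamate "
              "currency exclusion does not break the chain.",
    )


def _fig4() -> PaperFixture:
    """Synthetic stand-in for the 9-step lily glycolysis/pyruvate-dehydrogenase/
    TCA superpathway: only the step count is documented, so enzymes, genes and
    compounds are generated labels, never presented as the real pathway
    content."""
    db = PathwayDB()
    db, deg, truth = plant_linear_route(db, length=9, deg_coverage=set(range(9)), seed=4)
    name = "fig4_lily_superpathway"
    pwid = next(iter(db.pathways))
    return PaperFixture(
        name, db, deg, pwid,
        expected=dict(chain_length=9, route_length=9),
        notes="Synthetic 9-step stand-in for the lily glycolysis + pyruvate "
              "dehydrogenase + TCA superpathway (step count only).",
    )


_FACTORIES = {
    "fig4_lily_superpathway": _fig4,
    "fig5_ethanol_degradation_II": _fig5,
    "fig6_tca_variation": _fig6,
    "fig7_glycolysis_IV": _fig7,
    "fig8_kaempferol": _fig8,
    "fig9_rhamnose_kaempferol_glucoside": _fig9,
    "fig10_pa_biosynthesis": _fig10,
    "fig11_gaba_shunt": _fig11,
}

PAPER_FIXTURE_NAMES = tuple(_FACTORIES)


def paper_fixture(name: str) -> PaperFixture:
    """Return a packaged worked-example fixture by name."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(PAPER_FIXTURE_NAMES)}"
        ) from None
    return factory()
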