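# gecn — genome-scale enzyme correlation networks

`gecn` builds enzyme-level metabolic networks from pathway-genome databases
(PGDBs), overlays differential gene expression on them, and extracts the
consecutive-step metabolic routes whose every enzyme is encoded by a
differentially expressed gene (DEG). It implements the "guilt by
association" idea used to study pollen tube–stigma metabolic coupling in
*Arabidopsis* and maize: if the genes encoding the enzymes of consecutive
reaction steps all change expression together during a biological process,
that metabolic route is likely active in the process.

It is aimed at plant systems biologists who have (a) a BioCyc/PlantCyc-style
PGDB dump or an equivalent TSV bundle and (b) tables of differential
expression results, and who want route-level hypotheses rather than gene
lists.

## The model

**Enzyme coupling rule.** From the reaction table of a PGDB, build a graph
with enzymes as nodes. For enzymes E1 and E2, add the directed edge
E1 → E2 whenever

&nbsp;&nbsp;&nbsp;&nbsp;products(E1) ∩ substrates(E2) ∖ 𝒞 ≠ ∅,

where products/substrates range over the reactions each enzyme catalyzes
(reversible reactions contribute both orientations) and 𝒞 is the set of
**currency metabolites** — H+, ATP, ADP, AMP, NAD(H), NADP(H), CoA, O2,
CO2, NH3, glutamate and pyrophosphate by default — which take part in so
many reactions that they would couple nearly every enzyme pair. The linking
compounds are recorded on each edge. Matching is by exact compound token
("CoA" is currency; "acetyl-CoA" is not).

**DEG overlay.** A gene is a DEG when, in at least one contrast, fold
change ≥ 2 and FDR ≤ 1e-10 (both inclusive; thresholds configurable). DEGs
map to enzymes through the gene–enzyme table; the sub-interaction network
is the enzyme network induced on DEG-encoded enzymes with isolated nodes
dropped.

**Routes.** A route is an ordered list of reactions in which consecutive
steps share a non-currency linking metabolite and every step has at least
one DEG-encoded enzyme (any isozyme qualifies a step). `gecn` returns all
*maximal* simple routes — not extendable at either end, never a sub-path of
another returned route — either within a declared pathway's reaction chain
or de novo over the sub-network, with a deterministic enumeration cap.

Topology statistics (connected components, the connected-pairs count
Σ k(k−1)/2, degree tables) and EC-number-keyed cross-species network
overlap round out the toolkit.

## Worked example

The package ships small worked-example fixtures, including the glycolysis IV
(plant cytosol) pathway with the DEG gene lists observed in maize and
*Arabidopsis* stigmas during pollination:

```sh
gecn fixture --name fig7_glycolysis_IV --out-dir bundle
gecn build --db bundle --out net.sif
gecn map-degs --db bundle --deg bundle/deg.tsv --out sub.sif
gecn routes --db bundle --deg bundle/deg.tsv --pathway GLYCOLYSIS-IV-PWY --out routes.tsv
```

prints

```
fixture fig7_glycolysis_IV: 7 reactions, 7 enzymes, 24 DEG rows -> bundle
network: 7 nodes, 6 edges -> net.sif
DEGs: 24 genes; mapped 24 genes to 6 enzymes
sub-network: 5 nodes, 4 edges -> sub.sif
routes: 1 maximal route(s), longest 5 -> routes.tsv
```

Reading: the 7-step glycolysis chain couples 7 enzymes through 6 shared
intermediates. All 24 DEGs map onto 6 of the 7 enzymes — no DEG encodes
fructose-bisphosphate aldolase (EC 4.1.2.13, step 2) in either species — so
the aldolase node drops out and the longest DEG-covered route spans the 5
consecutive steps from glyceraldehyde-3-phosphate dehydrogenase to pyruvate
kinase. `routes.tsv` lists one row per step and gene, e.g.:

```
route  route_length  step  reaction_id    ec        enzyme_id  gene_id        contrast            log2fc  fdr    link_to_next
1      5             1     GLYC-IV-RXN-3  1.2.1.12  GAPDH      GRMZM2G046804  stigma_pollination  2.0     1e-12  1,3-bisphospho-D-glycerate
```

The same calls work on any TSV bundle or BioCyc attribute-value flat-file
directory (`compounds`, `reactions`, `proteins`/`enzymes`, `genes`,
optionally `pathways`); `gecn stats` and `gecn overlap` report topology and
cross-species EC overlap. Everything is also available as a library
(`import gecn`).

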