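# Methods

## Scope and data model

`gecn` works on a relational snapshot of a pathway-genome database:
compounds, reactions (EC number, substrate/product sets, reversibility,
pathway membership), enzymes (EC, name), a gene–enzyme table, and optional
pathways with a declared reaction order. Two input dialects are read — the
BioCyc-style attribute-value flat files commonly distributed as PGDB dumps,
and a canonical TSV bundle that is the package's ground-truth schema (the
flat-file reader maps onto it). Stoichiometry and compartments are ignored
throughout: the coupling rule below uses substrate/product *sets* only.

Real dumps are dirty, so loading is repair-oriented rather than strict:
compounds referenced by a reaction but missing from the compound table are
auto-registered with an empty name; gene links to unknown enzymes are
dropped; both with logged counts. Compound identity is the id token after
trimming, resolved case-insensitively (first-seen spelling wins). Names are
never used for matching — this is what keeps "CoA" from matching inside
"acetyl-CoA".

Reaction–enzyme attribution is the union of explicit links (the optional
`enzymes` column of `reactions.tsv`, or `CATALYZES` in flat files) and
exact non-empty EC equality between a reaction and an enzyme. Explicit
links exist because some real enzymes (e.g. the NRS/ER proteins of
dTDP-L-rhamnose biosynthesis) carry no EC number at all and could never be
attributed by EC matching.

## The enzyme coupling rule

Enzymes are nodes. For each ordered pair (E1, E2), E1 ≠ E2, an edge
E1 → E2 exists iff some product of a reaction of E1 equals some substrate
of a reaction of E2 and that compound is not a currency metabolite.
Reversible reactions contribute both orientations of their substrate and
product sets. Every linking compound is stored on the edge; at most one
edge per ordered pair (linking sets merged). Self-edges are excluded —
coupling is defined between two distinct enzymes. Enzymes with no reactions
remain as degree-0 nodes. Edges are built directed, because the rule is
asymmetric; an undirected collapse (orientations merged, linking sets
unioned) backs the topology statistics and SIF export.

The default currency set holds the classic carriers: H+, NADP, NADPH, NH3,
ATP, ADP, AMP, NAD, CoA, O2, CO2, pyrophosphate, plus three deliberate
entries. "ADH" appears in some currency lists but reads as alcohol
dehydrogenase — an enzyme, not a metabolite — so it is kept only as a
variant spelling of NADH and both tokens are excluded. "Glu" is mapped to
L-glutamate and both tokens are excluded; note currency status only
suppresses a compound *as a linking metabolite* — a route may still start
or end at glutamate, which is exactly what the GABA-shunt example does.
The set is an ordinary value: callers can replace or extend it, and
enlarging it can only remove edges (a property the tests exercise).

Whether isozymes (same EC, different loci) should share one node is not
decidable from the inputs; the package keeps one node per enzyme entity.
EC-level collapse happens only where it is forced — in cross-species
comparison, where EC is the only species-independent key.

## DEG calling and the sub-network

A DEG table row holds (gene, contrast, log2 fold change, FDR). A gene
qualifies when, in at least one contrast, |log2fc| ≥ log2(fc_min) and
fdr ≤ fdr_max, both boundaries inclusive; defaults fc_min = 2,
fdr_max = 1e-10. Fold changes are taken as provided — the package does not
recompute expression ratios from raw data; differential-expression testing
itself (DESeq2/limma territory) is upstream of this tool. Rows with missing
statistics are skipped with a warning, never silently.

DEG-encoded enzymes induce the sub-interaction network: edges survive iff
both endpoints are DEG-encoded, and nodes left without any incident edge
are removed by default. Dropping isolated nodes is what separates "enzymes
encoded by DEGs" from "sub-network nodes" in the summary counts; both
numbers are reported. A binary protein–protein interaction list can be
queried for the DEG interaction partners of any protein (undirected,
deduplicated, self-pairs rejected).

## Chains and routes

For a pathway with a declared reaction order, the chain follows that order;
where consecutive reactions share no non-currency compound the chain is
split with a warning. Without a declared order the chain is inferred: the
pathway's reactions form a directed graph under the non-currency
product → substrate relation, cycles are cut at the lexicographically
smallest edge inside a strongly connected component (with a warning), and
every maximal source-to-sink path of the resulting DAG becomes a chain — a
branched pathway therefore yields a chain cover, and `pathway_chain`
uniformly returns a list.

Route extraction operationalizes co-expression as joint DEG status: a step
qualifies if any of its isozyme genes is a DEG. Within chains, routes are
the maximal contiguous runs of qualifying steps. De novo, the search space
is the directed graph over qualifying reactions (restricted to the given
sub-network's enzymes) and the result is the set of maximal simple paths:
forward-unextendable paths are enumerated from every start node, and
backward-extendable ones are removed as strict contiguous sub-paths — below
the enumeration cap (default 10,000 recorded paths) this is exhaustive,
above it the result carries an explicit truncation flag. Returned routes
are sorted by length descending, then first reaction id; ties everywhere
break lexicographically, which makes every output byte-deterministic.

An optional correlation filter (`min_correlation`, off by default)
additionally requires consecutive steps to carry a gene pair whose
contrast-wise log2fc profiles have Pearson correlation at least the
threshold; pairs sharing fewer than 3 contrasts are not penalized, since
two points always correlate perfectly. The filter exists for datasets rich
in contrasts; the packaged examples have too few time points for it to be
meaningful.

Route reports emit one row per (step, gene) with the gene's strongest
evidence (smallest FDR, then largest |log2fc|); genes absent from the
table get blank statistics and a warning.

## Topology and cross-species overlap

Components are computed on the undirected view and ordered by size, then
smallest member. The connected-pairs statistic is Σ k(k−1)/2 over component
sizes — the number of unordered node pairs joined by some path. For two
organisms' networks, nodes collapse onto EC numbers (an EC pair is adjacent
if any representative enzyme pair is); the overlap graph keeps the ECs
present in both networks and the edges present in both collapses. Nodes
without an EC are excluded from keying and counted. Partial ECs like
`2.4.1.-` match only by exact string equality; `expand_partial=True`
rewrites each partial to the full ECs it covers before intersecting —
opt-in, because silent wildcard matching inflates overlaps irreproducibly.

## Synthetic data

The random generator emulates the *shape* of a PGDB at desk scale: each
reaction draws 1–3 substrates and 1–3 products from a compound pool,
reactions after the first reuse an earlier product (connectedness by
construction), currency metabolites attach to either side with probability
`p_currency_usage` (default 0.2), enzymes spread round-robin over reactions
(≤ 3 each), genes round-robin over enzymes. Defaults (30 compounds, 20
reactions, 20 enzymes, 40 genes, 30 % DEG fraction) keep brute-force
oracles — exhaustive ordered-pair scans and full simple-path enumeration —
affordable, which is the point of the module. Filler DEG rows draw log2fc
from (−0.5, 0.5) and FDR from (0.1, 1), so they can never pass the default
thresholds. Identical spec and seed give byte-identical bundles.

`plant_linear_route` appends a linear chain with fresh linking compounds
and a chosen DEG coverage pattern; the longest recovered route must equal
the longest contiguous covered run, for any length and gap pattern — the
pipeline's sharpest end-to-end invariant.

What the generator does **not** emulate: realistic degree distributions,
promiscuous hub metabolites below currency status, isozyme redundancy,
compartmentalization, or correlated expression structure. Passing tests on
synthetic data therefore demonstrate algorithmic correctness, not that any
particular biological conclusion transfers to a real PGDB.

The packaged worked examples transcribe small published pathway fragments
(ethanol degradation II, a TCA-cycle variation, glycolysis IV, kaempferol
and dTDP-L-rhamnose biosynthesis, phosphatidic-acid production, the GABA
shunt) with their DEG gene lists; gene ids, ECs and metabolite names follow
the printed text. Two deliberate quirks are preserved: the GABA-shunt
fixture's third step reads "succinate semialdehyde to GABA" as printed,
although the canonical shunt runs the opposite way; and the kaempferol
fixture's intermediate names are the standard phenylpropanoid/flavonoid
metabolites, since the source shows them only graphically. The
lily-superpathway entry is a synthetic stand-in — only its nine-step count
is documented, so its ids are generated labels and say so.

## Numerical and degenerate-input choices

No floating-point tolerance is involved anywhere: thresholds are inclusive
comparisons, and log2(fc_min) for the default fc_min = 2 is exact. Empty
inputs (empty DEG table, edgeless network, single-reaction pathway) flow
through every operation and are covered by tests. All orderings are
specified (insertion order for tables, lexicographic tie-breaks for graph
enumeration), so repeated runs produce identical bytes.

## Known limitations

Genome-scale organism databases (hundreds of pathways, thousands of
enzymes) load fine, but the acceptance examples run at worked-example
scale; the de-novo route enumerator is exponential in the worst case and
relies on its cap for adversarial graphs. The flat-file reader targets the
common public attribute-value dump dialect, not full ocelot/lisp exports,
citations or regulation records. Flux-balance reasoning, thermodynamic
feasibility and gap-filling are out of scope.
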