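# ahnet

Network analysis of anti-hypertensive drugs (AHs), their target-coding
genes (tc-genes), and the health conditions those genes associate with.

Hypertension is treated by a structurally diverse set of approved drugs.
`ahnet` implements a structure-aware network pipeline for studying how that
diversity maps onto target biology and disease: drugs are first clustered
into six structural groups by ring-pattern rules, and all downstream
analysis — target networks, functional profiles, disease associations,
combination trends — is carried out per group, turning one intractable
drug : gene : disease interactome into six readable sub-networks.

The package is aimed at computational pharmacologists and systems
biologists who work from tabular database exports (DrugBank-, ChEMBL-,
UniProt-, GAF- and Open-Targets-style TSV files) and want a reproducible,
tested implementation rather than a one-off spreadsheet analysis.

## What it computes

**Structural grouping.** Each molecule's SSSR ring-size multiset is matched
against six mutually exclusive patterns: g1 (4–6 rings, 2–3 five-membered),
g2 (2–3 rings, all six-membered), g3 (two rings, ≥ 1 five-membered), g4
(4–6 rings, total/six-membered < 1.4), g5 (two six-membered plus one five-
or seven-membered), g6 (monocyclic). Unmatched profiles stay `unassigned`.

**Validated drug–target edges.** An interaction is kept iff the target is
from *Homo sapiens*, reviewed, carried by a single unique UniProt
accession, and shows Ki, Kd or EC50 ≤ 10 μM (best measurement wins). Kept
edges form per-group bipartite drug : tc-gene networks, exportable as
SIF/GraphML for Cytoscape.

**Group overlap.** The percentage of common tc-genes between groups x and y
is the Jaccard percentage

```
Cg = 100 · n(tc-genesx ∩ tc-genesy) / n(tc-genesx ∪ tc-genesy)
```

reported as a symmetric 6×6 matrix with four-level glyph binning, plus a
three-set Venn decomposition of the overlapping groups.

**GO profiles.** Per group and GO aspect (MF/CC), the frequency of
occurrence FOc of a term is the number of the group's tc-genes annotated
with it, after excluding computationally inferred evidence (IEA/ND) and
exact-duplicate annotations. Terms with FOc ≥ 3 are retained (g1, the
smallest group: FOc ≥ 2). CC profiles additionally drop ubiquitous
plasma-membrane terms before normalising to proportions.

**Disease associations.** Open-Targets-style gene–disease records are
filtered at p ≤ 2.0e-9, scored as s = F·S·C (relative occurrence × effect
strength × confidence), and ranked per group by minimum p-value; the top-20
conditions are profiled by the number of supporting tc-genes.

**Combinations.** Clinical drug–drug combinations are canonicalized
(case-folding, salt stripping, MeSH-style synonym mapping), deduplicated as
unordered pairs, and summarised: per-drug partner statistics, partner-set
overlap, the distribution over group pairs with a trend ordering such as
`g2 > g6 > g1 > g3 = g4 = g5`, and per-pair shared-target counts.

A seeded synthetic-data generator (`ahnet.synthetic_data`) emulates all
five input tables with planted ground truth, so the entire pipeline is
testable offline.

## Worked example

```python
from ahnet.synthetic_data import SyntheticConfig, generate_bundle
from ahnet.structure_grouping import classify_cohort
from ahnet.network_build import filter_interactions, build_group_networks, degree_summary
from ahnet.overlap_stats import overlap_matrix, venn_triple

bundle = generate_bundle(SyntheticConfig(seed=7))
cohort = classify_cohort(bundle.drugs)
edges, dropped = filter_interactions(bundle.interactions)
networks = build_group_networks(edges, cohort.assignments)

for g, net in networks.items():
    s = degree_summary(net)
    print(f"{g}: {s['n_drugs']:2d} molecules, {s['n_genes']:2d} tc-genes, ratio {s['ratio']:.3f}")

sets = {g: set(n.tc_gene_set) for g, n in networks.items()}
print(overlap_matrix(sets).values.round(1).to_string())
print("triple-common tc-genes:", venn_triple(sets["g2"], sets["g4"], sets["g5"]).counts["abc"])
```

prints

```
g1:  8 molecules,  7 tc-genes, ratio 0.875
g2: 32 molecules, 60 tc-genes, ratio 1.875
g3: 24 molecules, 44 tc-genes, ratio 1.833
g4: 12 molecules, 31 tc-genes, ratio 2.583
g5: 14 molecules, 46 tc-genes, ratio 3.286
g6: 24 molecules, 16 tc-genes, ratio 0.667
       g1     g2     g3     g4     g5     g6
g1  100.0    0.0    0.0    0.0    0.0    0.0
g2    0.0  100.0    0.0   24.7   24.7    0.0
g3    0.0    0.0  100.0    0.0    0.0    0.0
g4    0.0   24.7    0.0  100.0   24.2    0.0
g5    0.0   24.7    0.0   24.2  100.0    0.0
g6    0.0    0.0    0.0    0.0    0.0  100.0
triple-common tc-genes: 14
```

The 114-drug cohort splits into groups of 8/32/24/12/14/24 molecules with
7/60/44/31/46/16 unique tc-genes: g1 and g6 have tc-genes/molecules < 1
(many drugs converging on few shared targets), while g2, g4 and g5 share
roughly a quarter of their tc-genes pairwise, 14 genes being common to all
three.

The same run is available from the shell:

```sh
ahnet simulate --seed 7 --outdir bundle
ahnet run-all --drugs bundle/drugs.tsv --interactions bundle/interactions.tsv \
  --go-annotations bundle/go_annotations.tsv --associations bundle/associations.tsv \
  --combination-pairs bundle/combinations.tsv --name-map bundle/name_map.tsv \
  --outdir out
```

which writes per-stage TSV/SIF/GraphML artifacts and a machine-readable
`out/report.json`.

## Layout

| Module | Role |
| --- | --- |
| `ahnet.structure_grouping` | ring-pattern rules, cohort classification |
| `ahnet.network_build` | inclusion-criteria filter, bipartite networks, export |
| `ahnet.overlap_stats` | Cg matrix, glyph binning, Venn decomposition |
| `ahnet.go_profile` | evidence filtering, FOc tables, CC distributions |
| `ahnet.disease_assoc` | p-value filter, s = F·S·C, top-k condition ranking |
| `ahnet.combinations` | name canonicalization, partner stats, group trend |
| `ahnet.synthetic_data` | seeded five-table generator with ground truth |
| `ahnet.pipeline_cli` | orchestration, validation, `ahnet` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
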