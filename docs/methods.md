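# Methods

This note documents the models, parameter choices and numerical conventions
behind `ahnet`, and what the synthetic-data tests do and do not establish
about behaviour on real database exports.

## Structural grouping

Molecules are classified from their SSSR (smallest set of smallest rings)
ring-size multiset alone. SSSR is our documented convention for bridged,
spiro and macrocyclic systems: each smallest ring counts once, fused
systems contribute one ring per smallest ring. The six rules are:

| group | rule |
| --- | --- |
| g1 | 4–6 rings, of which 2–3 are five-membered |
| g2 | 2–3 rings, all six-membered |
| g3 | exactly 2 rings, ≥ 1 five-membered |
| g4 | 4–6 rings, total/six-membered ratio < 1.4 |
| g5 | exactly 3 rings: two six-membered + one five- or seven-membered |
| g6 | monocyclic |

Two conventions deserve note. First, the g4 ratio is *undefined* when a
molecule has no six-membered ring; the rule then simply fails rather than
raising a division error. Second, profiles matching no rule are labelled
`unassigned` instead of being forced to a nearest group — structural
clustering of this kind carries a few percent of assignment error, and
silent forcing would hide it. The rules are mutually exclusive: the test
suite enumerates all 6,435 multisets with sizes 3–9 and up to eight rings
and verifies that no profile matches two rules, which also makes the fixed
rule-evaluation order (g6, g3, g2, g5, g1, g4) irrelevant.

The core consumes ring multisets directly, so the package needs no
chemistry dependency; `ring_sizes_from_smiles` is an optional rdkit adapter
(one test uses it as an independent ring-perception oracle on losartan,
whose phenyl-imidazole/tetrazole system yields {5,5,6,6} → g1).

## Interaction filtering

A drug–target record survives iff (i) organism is *Homo sapiens*
(case-insensitive), (ii) review status is `reviewed`, (iii) the accession
resolves to a single primary UniProt accession — isoform suffixes
(`P30556-2`) collapse to the primary, while multi-accession entries
(`Q1;Q2`) are rejected as non-unique — and (iv) the best activity across
the admitted endpoints (Ki, Kd, EC50; IC50 excluded by default but
configurable) is ≤ 10 μM. The bound is inclusive: exactly 10 μM passes.
Units are normalised to nM (μM × 1000). Multiple measurements per
(drug, target) collapse to the minimum — the criterion is satisfied if any
qualifying measurement exists. The filter is monotone in the threshold and
idempotent; malformed rows become per-row error records, never aborts.

One gene symbol is expected per accession, taken from the input table;
conflicting symbols for one accession produce error records for the
affected rows.

Per-group networks are bipartite (drugs × genes). Drugs whose edges were
all filtered away remain as isolated nodes and count in the denominator of
the tc-genes/molecules ratio; a group with zero drugs has an undefined
ratio reported as `None`.

## Overlap statistic

Cg is the Jaccard index in percent, computed via the inclusion–exclusion
union identity. The overlap of two empty sets is flagged undefined (NaN)
rather than 0 or 100 — neither value has meaning and real cohorts never hit
the case. The four glyph levels (open / quarter / half / full circle) are a
qualitative rendering; the numeric bin edges 12.5 / 37.5 / 75 are this
package's choice, placed midway between the nominal levels 0/25/50/100,
and are configurable.

## GO profiles

"Computationally inferred" evidence is operationalised as the code set
{IEA, ND} (IEA being the canonical non-curated code; ND carries no data);
the set is configurable. Redundancy removal is exact-triple deduplication
on (gene, aspect, term) — no merging of near-synonymous terms and no
ontology-graph propagation, since the analysis works on raw annotation
frequencies, not enrichment statistics. FOc counts distinct genes, not
annotation rows, so it is invariant to row order and duplicated input.
Retention cutoffs: FOc ≥ 3, relaxed to ≥ 2 for g1 because with only seven
genes a requirement of three supporting genes would empty the profile.
CC proportions are formed after removing the ubiquitous terms
{plasma membrane, integral component of plasma membrane, membrane}
(parameter), which annotate essentially every drug target and mask
group-specific localisation.

## Disease associations

The association score s = F·S·C multiplies relative evidence occurrence,
effect strength and confidence, each in [0, 1]; it is reported alongside
every retained record but never used for ranking — conditions are ranked
purely by minimum p-value across the group's genes, ties broken
alphabetically by disease name, truncated to the top 20. Disease identity
is keyed on the ontology id when present, else the name.

The default p cutoff is 2.0e-9, inclusive. `derive_p_threshold` documents
where such a cutoff comes from: it returns the maximum over groups of the
within-group minimum p — the loosest threshold at which every group
retains at least one association. This is one of two defensible readings
of "the maximum p-value present in all six groups"; the pipeline therefore
always accepts an explicit threshold override rather than silently
deriving one.

## Combinations

Names are canonicalized by case-folding, stripping trailing salt/hydrate
suffixes (packaged editable list in `ahnet/data/salt_suffixes.txt`), and
applying a raw→canonical synonym map; unmapped names pass through flagged.
Pairs are unordered and deduplicated; self-pairs are errors; pairs
involving a drug without validated targets are excluded with a report
entry. Partner overlap between two drugs is the Jaccard percentage of
their partner sets; "including each other" is operationalised as adding
both drugs to the shared set when they are themselves paired — the
definition is not standard, so the flag makes both readings computable.
The group trend orders groups by the number of pairs involving at least
one member, with equal counts rendered as `=` classes.

## Synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:
114 drugs in groups of 8/32/24/12/14/24; gene sets of 7/60/44/31/46/16
realising pairwise Jaccard overlap ≈ 25% between g2–g4, g2–g5 and g4–g5
through a 14-gene triple-shared core plus pair-specific extras (4/7/1),
with all other group pairs disjoint; one dominant MF term per group
clearing the FOc rule; twenty sub-threshold conditions per group; 21
combination pairs realising the trend g2 > g6 > g1 > g3 = g4 = g5 with hub
drugs at 13/21 (61.9%) and 4/21 (19.0%) of pairs and five pairs (23.8%)
within g2.

Distributional choices the emulated sources leave open, fixed once:
bioactivities log-uniform on [1, 9000] nM with ~30% expressed in μM
(exercising unit conversion) plus one planted edge at exactly 10 μM
(exercising the inclusive boundary); association p-values log-uniform on
[1e-30, 2e-9] with decoys on (1e-8, 1e-3]; evidence factors F, S, C
uniform on (0.2, 1) so scores are never degenerate. Decoy interaction rows
each violate exactly one inclusion criterion (organism, review status,
accession uniqueness, activity), enabling per-criterion filter tests.

Two structural decisions make round-trip recovery well-posed rather than
probabilistic. Group-specific disease conditions sample genes only from a
group's *exclusive* genes; the only conditions touching shared genes are
the deliberately shared ones (anxiety over all 14 core genes, sleep
disorder over 11 of them). Likewise dominant/mid/rare MF terms are
annotated over exclusive genes only, so a planted dominant term is
strictly the top retained term of its group at every seed; the ubiquitous
CC terms and the IEA-coded decoy span the full overlapping sets,
preserving the fact that shared genes share annotations.

What the synthetic bundle does **not** emulate: real chemistry (ring
multisets are sampled constructively, not perceived from structures),
correlated annotation patterns between related genes, ontology structure
among GO terms or EFO diseases, and literature-driven biases in which
gene–disease pairs get measured. Passing the recovery tests therefore
demonstrates correctness of the pipeline's filtering, counting and ranking
logic under known ground truth — not that biological conclusions transfer
to any particular database snapshot.

## Problem sizes and determinism

All analyses run on the 114-drug bundle (≈ 270 interaction rows, ≈ 850
annotations, ≈ 1,900 association rows); the full pipeline completes in
about a second, and the exhaustive rule-disjointness enumeration covers
6,435 profiles. Randomness flows through a single seeded numpy generator;
the same config and seed regenerate byte-identical tables, and a pipeline
rerun on the same inputs writes byte-identical artifacts.

## Known limitations

* Ring counting is SSSR-only; a source that counted envelope rings of
  fused systems differently would shift borderline g1/g4 assignments.
* Name canonicalization handles case, whitespace, trailing salt suffixes
  and explicit synonyms, but not spelling variants or brand names absent
  from the map.
* `derive_p_threshold` requires every group to be non-empty; the pipeline
  falls back to the explicit threshold when any group view is empty.
* The CC proportion excludes generic terms by exact (case-insensitive)
  name match, not by GO-graph ancestry.
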