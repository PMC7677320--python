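"""Seeded synthetic input bundles with planted ground truth.

Emulates the five tabular inputs of the drug : tc-gene : disease analysis —
a drug table with ring-size profiles, a drug–target interaction table, a
GO annotation table, a gene–disease association table, and a clinical
combination list — with a known planted structure so every pipeline stage
can be validated round-trip without any database download.

Default parameters reproduce the study conditions:

* group sizes 8/32/24/12/14/24 and per-group tc-gene counts
  7/60/44/31/46/16 for g1..g6;
* pairwise gene-set overlap of roughly one quarter (Jaccard ≈ 25%) between
  g2–g4, g2–g5 and g4–g5, realised as a 14-gene triple-shared core plus
  pair-specific extras (4, 7, 1), and essentially zero elsewhere;
* one dominant molecular-function term per group that clears the FOc
  retention rule, amid sub-threshold and computationally inferred decoys;
* twenty sub-threshold (p ≤ 2.0e-9) health conditions per group, including
  shared conditions over the 14 common genes ("anxiety": all 14;
  "sleep disorder": 11 of 14), amid above-threshold decoys;
* 21 deduplicated combination pairs realising the group trend
  g2 > g6 > g1 > g3 = g4 = g5, with hub drugs at 13/21 and 4/21 pairs and
  about one quarter of pairs within g2.

All randomness flows from one seeded :func:`numpy.random.default_rng`
generator; the same config and seed regenerate byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_grouping import GROUPS, assign_group, make_ring_profile

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_ring_multiset",
    "generate_bundle",
    "write_bundle",
]

_EXPERIMENTAL_EVIDENCE = ("IDA", "IMP", "IPI", "EXP")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic bundle; defaults are the study conditions."""

    seed: int = 7
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"g1": 8, "g2": 32, "g3": 24, "g4": 12, "g5": 14, "g6": 24}
    )
    genes_per_group: dict[str, int] = field(
        default_factory=lambda: {"g1": 7, "g2": 60, "g3": 44, "g4": 31, "g5": 46, "g6": 16}
    )
    #: Genes shared by g2, g4 and g5 together (Venn centre).
    triple_common: int = 14
    #: Extra genes shared by exactly one overlapping pair.
    pair_extra: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("g2", "g4"): 4, ("g2", "g5"): 7, ("g4", "g5"): 1}
    )
    #: Planted sub-threshold health conditions per group (ranking cutoff).
    n_conditions: int = 20
    #: Above-threshold decoy conditions per group.
    n_decoy_conditions: int = 8
    #: p-value range of planted associations (log-uniform).
    p_min: float = 1e-30
    p_max: float = 2.0e-9
    #: Decoy interaction rows per failure mode.
    n_decoys_per_criterion: int = 2

    def validate(self) -> None:
        for name, d in (("group_sizes", self.group_sizes), ("genes_per_group", self.genes_per_group)):
            for g in GROUPS:
                if d.get(g, 0) <= 0:
                    raise ValueError(f"{name}[{g!r}] must be positive")
        shared = {g: 0 for g in GROUPS}
        for (a, b), n in self.pair_extra.items():
            if n < 0:
                raise ValueError("pair_extra counts must be >= 0")
            shared[a] += n
            shared[b] += n
        for g in ("g2", "g4", "g5"):
            shared[g] += self.triple_common
        for g in GROUPS:
            if shared[g] >= self.genes_per_group[g]:
                raise ValueError(
                    f"overlap targets infeasible: group {g} needs "
                    f"{shared[g]} shared genes but has only "
                    f"{self.genes_per_group[g]} in total"
                )


@dataclass
class SyntheticBundle:
    """The five input tables plus the planted ground truth."""

    drugs: pd.DataFrame
    interactions: pd.DataFrame
    go_annotations: pd.DataFrame
    associations: pd.DataFrame
    combination_pairs: pd.DataFrame
    name_map: pd.DataFrame
    ground_truth: dict


def generate_ring_multiset(group: str, rng: np.random.Generator) -> tuple[int, ...]:
    """Sample a ring-size multiset satisfying exactly one group's rule.

    Constructive (no rejection failures); the classifier round-trips every
    draw back to ``group``.
    """
    if group == "g6":  # monocyclic
        sizes = [int(rng.choice([5, 6, 7]))]
    elif group == "g3":  # two rings, >= 1 five-membered
        sizes = [5, int(rng.choice([3, 4, 5, 7, 8]))]
        # a 5+6 bicycle would also be g3, but 6 as partner keeps it g3 too
        if rng.random() < 0.5:
            sizes = [5, 6]
    elif group == "g2":  # 2-3 rings, all six-membered
        sizes = [6] * int(rng.choice([2, 3]))
    elif group == "g5":  # two six + one five- or seven-membered
        sizes = [6, 6, int(rng.choice([5, 7]))]
    elif group == "g1":  # 4-6 rings with 2-3 five-membered
        total = int(rng.choice([4, 5, 6]))
        n5 = int(rng.choice([2, 3]))
        others = [int(rng.choice([6, 7, 8])) for _ in range(total - n5)]
        sizes = [5] * n5 + others
    elif group == "g4":  # 4-6 rings, total/six < 1.4, avoiding the g1 pattern
        total = int(rng.choice([4, 5, 6]))
        n6 = {4: 3, 5: 4, 6: 5}[total]  # smallest n6 with total/n6 < 1.4
        if rng.random() < 0.5:
            n6 = total
        others = [int(rng.choice([3, 4, 7, 8])) for _ in range(total - n6)]
        sizes = [6] * n6 + others
    else:
        raise ValueError(f"cannot generate rings for group {group!r}")
    assert assign_group(make_ring_profile(sizes)) == group
    return tuple(sorted(sizes))


def _gene_universe(config: SyntheticConfig) -> tuple[dict[str, list[str]], dict]:
    """Construct per-group gene lists realising the planted overlaps."""
    core = [f"COM{i:02d}" for i in range(1, config.triple_common + 1)]
    extras = {
        pair: [f"X{pair[0][-1]}{pair[1][-1]}{i:02d}" for i in range(1, n + 1)]
        for pair, n in config.pair_extra.items()
    }
    gene_sets: dict[str, list[str]] = {}
    exclusive: dict[str, list[str]] = {}
    for g in GROUPS:
        shared: list[str] = []
        if g in ("g2", "g4", "g5"):
            shared.extend(core)
        for (a, b), genes in extras.items():
            if g in (a, b):
                shared.extend(genes)
        n_unique = config.genes_per_group[g] - len(shared)
        uniq = [f"{g.upper()}U{i:02d}" for i in range(1, n_unique + 1)]
        exclusive[g] = uniq
        gene_sets[g] = shared + uniq
    meta = {"core": core, "extras": {f"{a}-{b}": v for (a, b), v in extras.items()},
            "exclusive": exclusive}
    return gene_sets, meta


def _interaction_rows(
    config: SyntheticConfig,
    rng: np.random.Generator,
    drugs_by_group: dict[str, list[str]],
    gene_sets: dict[str, list[str]],
    accession_of: dict[str, str],
) -> tuple[list[dict], dict]:
    """Edges covering every planted gene, plus per-criterion decoy rows."""
    rows: list[dict] = []
    truth_edges: dict[str, set[str]] = {}

    def add_row(drug, gene, acc, organism="Homo sapiens", status="reviewed",
                endpoint=None, value=None, unit=None):
        if endpoint is None:
            endpoint = str(rng.choice(["Ki", "Kd", "EC50"]))
        if value is None:
            nm = float(np.exp(rng.uniform(np.log(1.0), np.log(9000.0))))
            if rng.random() < 0.3:
                value, unit = round(nm / 1000.0, 4), "uM"
            else:
                value, unit = round(nm, 2), "nM"
        rows.append(
            {
                "drug_id": drug,
                "accession": acc,
                "gene_symbol": gene,
                "organism": organism,
                "review_status": status,
                "endpoint": endpoint,
                "value": value,
                "unit": unit,
            }
        )

    boundary_edge = None
    for g in GROUPS:
        drugs = drugs_by_group[g]
        genes = list(gene_sets[g])
        # coverage: deal genes round-robin over shuffled drugs
        order = list(rng.permutation(len(drugs)))
        for j, gene in enumerate(genes):
            drug = drugs[order[j % len(drugs)]]
            if boundary_edge is None and g == "g3" and gene.startswith("G3U"):
                # exact-boundary bioactivity: 10 uM, kept by the inclusive rule
                add_row(drug, gene, accession_of[gene],
                        endpoint="EC50", value=10.0, unit="uM")
                boundary_edge = {"drug_id": drug, "gene_symbol": gene}
            else:
                add_row(drug, gene, accession_of[gene])
            truth_edges.setdefault(drug, set()).add(gene)
        # extra edges for network texture
        n_extra = max(1, len(drugs) // 2)
        for _ in range(n_extra):
            drug = drugs[int(rng.integers(len(drugs)))]
            gene = genes[int(rng.integers(len(genes)))]
            if boundary_edge and gene == boundary_edge["gene_symbol"]:
                continue  # keep the boundary edge's 10 uM row its only row
            add_row(drug, gene, accession_of[gene])
            truth_edges.setdefault(drug, set()).add(gene)
        # every drug must carry >= 1 validated target (combination criterion)
        for drug in drugs:
            if drug not in truth_edges:
                gene = genes[int(rng.integers(len(genes)))]
                if boundary_edge and gene == boundary_edge["gene_symbol"]:
                    gene = genes[-1]
                add_row(drug, gene, accession_of[gene])
                truth_edges.setdefault(drug, set()).add(gene)

    # decoys: each violates exactly one inclusion criterion
    decoy_specs = [
        ("organism", dict(organism="Rattus norvegicus")),
        ("review", dict(status="unreviewed")),
        ("activity", dict(endpoint="Ki", value=15.0, unit="uM")),
        ("uniqueness", dict()),
    ]
    all_drugs = [d for ds in drugs_by_group.values() for d in ds]
    n_decoys = 0
    for i in range(config.n_decoys_per_criterion):
        for kind, kw in decoy_specs:
            drug = all_drugs[int(rng.integers(len(all_drugs)))]
            gene = f"DECOY_{kind.upper()}{i}"
            acc = (
                f"Q9{i}001;Q9{i}002" if kind == "uniqueness" else f"D{kind[:3].upper()}{i:03d}"
            )
            add_row(drug, gene, acc, **kw)
            n_decoys += 1

    truth = {
        "edges_by_drug": {d: sorted(s) for d, s in truth_edges.items()},
        "boundary_edge": boundary_edge,
        "n_decoy_rows": n_decoys,
    }
    return rows, truth


def _go_rows(
    config: SyntheticConfig,
    rng: np.random.Generator,
    gene_sets: dict[str, list[str]],
    exclusive: dict[str, list[str]],
) -> tuple[list[dict], dict]:
    """GO annotations with one dominant MF term per group plus decoys.

    Dominant, mid-rank and sub-threshold MF terms are annotated over each
    group's exclusive genes only, so a planted dominant term is strictly
    the highest-FOc retained term of its group regardless of the seed;
    ubiquitous CC terms and the computationally inferred decoy span the
    full (overlapping) gene sets, as shared genes share annotations.
    """
    rows: list[dict] = []
    dominant: dict[str, dict] = {}
    term_no = 0

    def term_id() -> str:
        nonlocal term_no
        term_no += 1
        return f"GO:{1000000 + term_no:07d}"

    def annotate(gene, aspect, tid, tname, evidence):
        rows.append(
            {
                "gene_symbol": gene,
                "aspect": aspect,
                "term_id": tid,
                "term_name": tname,
                "evidence_code": evidence,
            }
        )

    mf_names = {
        "g1": "DNA binding", "g2": "voltage-gated calcium channel activity",
        "g3": "G protein-coupled receptor activity",
        "g4": "metal ion binding", "g5": "adrenergic receptor activity",
        "g6": "epinephrine binding",
    }
    cc_names = {
        "g1": "nucleoplasm", "g2": "voltage-gated calcium channel complex",
        "g3": "synapse", "g4": "dendrite", "g5": "axon terminus",
        "g6": "chromaffin granule",
    }
    threshold = {"g1": 2}
    for g in GROUPS:
        genes = list(gene_sets[g])
        pool = list(exclusive[g])
        n = len(genes)
        n_pool = len(pool)
        cutoff = threshold.get(g, 3)
        # dominant MF term: strictly the highest surviving FOc
        k_dom = min(max(cutoff + 2, n_pool // 2), n_pool)
        tid, tname = term_id(), mf_names[g]
        picks = list(rng.choice(pool, size=k_dom, replace=False))
        for gene in picks:
            annotate(gene, "MF", tid, tname, str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        # duplicate one annotation under a second evidence code (dedup fodder)
        annotate(picks[0], "MF", tid, tname, "IMP")
        dominant[g] = {"term_id": tid, "term_name": tname, "foc": k_dom}
        # mid-rank surviving terms, strictly below the dominant FOc
        for m in range(2):
            k_mid = k_dom - 1 - m
            if k_mid < cutoff:
                continue
            mid_id, mid_name = term_id(), f"{g} secondary activity {m + 1}"
            for gene in rng.choice(pool, size=k_mid, replace=False):
                annotate(gene, "MF", mid_id, mid_name,
                         str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        # sub-threshold decoy MF terms
        for m in range(3):
            k_low = max(1, cutoff - 1)
            low_id, low_name = term_id(), f"{g} rare activity {m + 1}"
            for gene in rng.choice(pool, size=min(k_low, n_pool), replace=False):
                annotate(gene, "MF", low_id, low_name,
                         str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        # computationally inferred decoy: would dominate if not excluded
        iea_id, iea_name = term_id(), f"{g} inferred kinase activity"
        for gene in rng.choice(genes, size=max(2, int(0.8 * n)), replace=False):
            annotate(gene, "MF", iea_id, iea_name, "IEA")
        # CC: ubiquitous membrane terms + one group-specific compartment
        pm_id, ic_id = "GO:0005886", "GO:0005887"
        for gene in rng.choice(genes, size=max(2, int(0.7 * n)), replace=False):
            annotate(gene, "CC", pm_id, "plasma membrane",
                     str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        for gene in rng.choice(genes, size=max(1, int(0.4 * n)), replace=False):
            annotate(gene, "CC", ic_id, "integral component of plasma membrane",
                     str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        cc_id, cc_name = term_id(), cc_names[g]
        for gene in rng.choice(genes, size=max(cutoff + 1, n // 2), replace=False):
            annotate(gene, "CC", cc_id, cc_name,
                     str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
        other_id, other_name = term_id(), f"{g} minor compartment"
        for gene in rng.choice(genes, size=max(1, n // 4), replace=False):
            annotate(gene, "CC", other_id, other_name,
                     str(rng.choice(_EXPERIMENTAL_EVIDENCE)))
    return rows, {"dominant_mf": dominant}


def _association_rows(
    config: SyntheticConfig,
    rng: np.random.Generator,
    gene_sets: dict[str, list[str]],
    exclusive: dict[str, list[str]],
    core: list[str],
) -> tuple[list[dict], dict]:
    """Planted sub-threshold conditions per group amid decoys.

    Group-specific conditions draw genes only from the group's exclusive
    genes, so they never leak into another group's view; the shared
    conditions over the 14-gene core appear in g2, g4 and g5 by design.
    """
    rows: list[dict] = []
    seen: set[tuple[str, str]] = set()
    efo_no = 0

    def efo() -> str:
        nonlocal efo_no
        efo_no += 1
        return f"EFO:{7000000 + efo_no:07d}"

    def add(gene, did, dname, p):
        if (gene, did) in seen:
            return
        seen.add((gene, did))
        rows.append(
            {
                "gene_symbol": gene,
                "disease_id": did,
                "disease_name": dname,
                "p_value": p,
                "F": round(float(rng.uniform(0.2, 1.0)), 4),
                "S": round(float(rng.uniform(0.2, 1.0)), 4),
                "C": round(float(rng.uniform(0.2, 1.0)), 4),
            }
        )

    def planted_p() -> float:
        return float(
            np.exp(rng.uniform(np.log(config.p_min), np.log(config.p_max)))
        )

    def decoy_p() -> float:
        return float(np.exp(rng.uniform(np.log(config.p_max * 5), np.log(1e-3))))

    anxiety = {"id": efo(), "name": "anxiety"}
    sleep = {"id": efo(), "name": "sleep disorder"}
    # three core genes stand apart from the sleep-disorder association,
    # mirroring the alpha-1 adrenergic exception among the common genes
    sleep_excluded = core[:3]
    for gene in core:
        add(gene, anxiety["id"], anxiety["name"], planted_p())
        if gene not in sleep_excluded:
            add(gene, sleep["id"], sleep["name"], planted_p())

    planted: dict[str, list[dict]] = {}
    full_condition: dict[str, dict] = {}
    for g in GROUPS:
        pool = exclusive[g]
        n_specific = config.n_conditions - (2 if g in ("g2", "g4", "g5") else 0)
        conds = []
        for i in range(n_specific):
            did, dname = efo(), f"{g} condition {i + 1:02d}"
            if i == 0:  # full-coverage condition over the exclusive genes
                chosen = list(pool)
                full_condition[g] = {"id": did, "name": dname, "n_genes": len(pool)}
            else:
                m = int(rng.integers(3, max(4, len(pool) + 1)))
                m = min(m, len(pool))
                chosen = list(rng.choice(pool, size=m, replace=False))
            for gene in chosen:
                add(gene, did, dname, planted_p())
            conds.append({"id": did, "name": dname})
        if g in ("g2", "g4", "g5"):
            conds.extend([anxiety, sleep])
        planted[g] = conds
        # decoy conditions: above threshold, excluded by the p filter
        for i in range(config.n_decoy_conditions):
            did, dname = efo(), f"{g} decoy condition {i + 1:02d}"
            m = min(max(2, len(pool) // 3), len(pool))
            for gene in rng.choice(pool, size=m, replace=False):
                add(gene, did, dname, decoy_p())
    truth = {
        "planted_conditions": {
            g: sorted(c["id"] for c in conds) for g, conds in planted.items()
        },
        "full_coverage_condition": full_condition,
        "anxiety": anxiety,
        "sleep_disorder": {**sleep, "excluded_genes": sleep_excluded},
    }
    return rows, truth


def _combination_layout(drugs_by_name: dict[str, list[str]]) -> list[tuple[str, str]]:
    """Fixed 21-pair layout realising the planted group trend.

    Hub A (g2) sits in 13 pairs (61.9%), hub B (g2) in 4 (19.0%); 5 pairs
    lie within g2 (23.8%), 10 span g2–g6, 3 span g1–g2 and one each spans
    g2 with g3, g4 and g5 — giving involvement g2:21 > g6:10 > g1:3 >
    g3 = g4 = g5:1.
    """
    g1, g2, g3, g4, g5, g6 = (drugs_by_name[g] for g in GROUPS)
    A, B, c1, c2 = g2[0], g2[1], g2[2], g2[3]
    pairs = [
        (A, B), (A, c1), (A, c2), (B, c1), (B, c2),  # within g2
        *[(A, f) for f in g6[:7]], (B, g6[7]), (g2[4], g6[8]), (g2[5], g6[9]),
        (A, g1[0]), (A, g1[1]), (A, g1[2]),  # g1–g2
        (g2[6], g3[0]), (g2[7], g4[0]), (g2[8], g5[0]),
    ]
    assert len(pairs) == 21 and len(set(map(frozenset, pairs))) == 21
    return pairs


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate the five-table synthetic bundle with ground truth.

    Deterministic: the same config (and seed) yields identical tables.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # drugs -----------------------------------------------------------------
    drug_rows = []
    drugs_by_group: dict[str, list[str]] = {}
    names_by_group: dict[str, list[str]] = {}
    idx = 0
    for g in GROUPS:
        ids, names = [], []
        for i in range(config.group_sizes[g]):
            idx += 1
            did, name = f"SD{idx:04d}", f"{g}med{i + 1:02d}"
            rings = generate_ring_multiset(g, rng)
            drug_rows.append(
                {
                    "drug_id": did,
                    "name": name,
                    "ring_sizes": ",".join(map(str, rings)),
                }
            )
            ids.append(did)
            names.append(name)
        drugs_by_group[g] = ids
        names_by_group[g] = names
    drugs = pd.DataFrame(drug_rows)

    # genes & interactions --------------------------------------------------
    gene_sets, gene_meta = _gene_universe(config)
    all_genes = sorted({g for gs in gene_sets.values() for g in gs})
    accession_of = {gene: f"Q{20000 + i:05d}" for i, gene in enumerate(all_genes)}
    inter_rows, inter_truth = _interaction_rows(
        config, rng, drugs_by_group, gene_sets, accession_of
    )
    interactions = pd.DataFrame(inter_rows)

    # GO annotations --------------------------------------------------------
    go_rows, go_truth = _go_rows(config, rng, gene_sets, gene_meta["exclusive"])
    go_annotations = pd.DataFrame(go_rows)

    # associations ----------------------------------------------------------
    assoc_rows, assoc_truth = _association_rows(
        config, rng, gene_sets, gene_meta["exclusive"], gene_meta["core"]
    )
    associations = pd.DataFrame(assoc_rows)
    per_group_min = {
        g: min(
            r["p_value"] for r in assoc_rows if r["gene_symbol"] in set(gene_sets[g])
        )
        for g in GROUPS
    }

    # combinations & name map ----------------------------------------------
    pairs = _combination_layout(names_by_group)
    name_map_rows: dict[str, str] = {}
    raw_pairs = []
    for i, (a, b) in enumerate(pairs):
        ra, rb = a, b
        if i % 4 == 0:
            ra = a.upper() + " "  # case/space noise
        if i % 5 == 0:
            rb = f"{b} hydrochloride"  # salt suffix
        if i % 7 == 0:
            ra = f"{a}-syn"  # synonym needing the MeSH-style map
            name_map_rows[ra] = a
        raw_pairs.append({"drug_a": ra, "drug_b": rb})
    # one duplicated pair in reversed orientation (dedup fodder)
    raw_pairs.append({"drug_a": pairs[0][1], "drug_b": pairs[0][0]})
    combination_pairs = pd.DataFrame(raw_pairs)
    name_map = pd.DataFrame(
        [{"raw": r, "canonical": c} for r, c in sorted(name_map_rows.items())],
        columns=["raw", "canonical"],
    )

    hubs = {"primary": pairs[0][0], "secondary": pairs[0][1]}
    ground_truth = {
        "seed": config.seed,
        "group_of_drug": {
            d: g for g, ds in drugs_by_group.items() for d in ds
        },
        "group_sizes": dict(config.group_sizes),
        "gene_sets": {g: sorted(gene_sets[g]) for g in GROUPS},
        "genes_per_group": dict(config.genes_per_group),
        "gene_meta": gene_meta,
        "accession_of_gene": accession_of,
        "interactions": inter_truth,
        "go": go_truth,
        "associations": {**assoc_truth, "per_group_min_p": per_group_min,
                         "derived_threshold": max(per_group_min.values())},
        "combinations": {
            "pairs": [sorted(p) for p in map(list, pairs)],
            "trend": [["g2"], ["g6"], ["g1"], ["g3", "g4", "g5"]],
            "hubs": hubs,
            "within_g2_pct": 100.0 * 5 / 21,
        },
    }
    return SyntheticBundle(
        drugs=drugs,
        interactions=interactions,
        go_annotations=go_annotations,
        associations=associations,
        combination_pairs=combination_pairs,
        name_map=name_map,
        ground_truth=ground_truth,
    )


_TABLE_FILES = {
    "drugs": "drugs.tsv",
    "interactions": "interactions.tsv",
    "go_annotations": "go_annotations.tsv",
    "associations": "associations.tsv",
    "combination_pairs": "combinations.tsv",
    "name_map": "name_map.tsv",
}


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write the bundle's tables as TSV plus ground_truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _TABLE_FILES.items():
        path = outdir / fname
        getattr(bundle, attr).to_csv(path, sep="\t", index=False)
        paths[attr] = path
    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(bundle.ground_truth, indent=1, sort_keys=True))
    paths["ground_truth"] = gt_path
    return paths
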