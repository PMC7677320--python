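"""Bioactivity filtering and per-group bipartite drug–gene network assembly.

A raw drug–target interaction table (ChEMBL/UniProt-style export) is reduced
to validated edges by the study's inclusion criteria: the target must be
human, reviewed, carried by a single unique UniProt accession, and show
Ki, Kd or EC50 bioactivity of at most 10 μM (any qualifying measurement
suffices; the best — minimum — value is kept). Validated edges are then
grouped by each drug's structural group into bipartite drug : tc-gene
networks, whose gene-set sizes and tc-genes/molecules ratios mirror the
per-group summary table of the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .structure_grouping import GROUPS, UNASSIGNED

__all__ = [
    "INTERACTION_COLUMNS",
    "DEFAULT_THRESHOLD_NM",
    "MissingActivityError",
    "normalize_activity",
    "to_nanomolar",
    "filter_interactions",
    "GroupNetwork",
    "build_group_networks",
    "degree_summary",
    "export_network",
    "load_edge_set",
]

#: Expected columns of the raw interaction table.
INTERACTION_COLUMNS = (
    "drug_id",
    "accession",
    "gene_symbol",
    "organism",
    "review_status",
    "endpoint",
    "value",
    "unit",
)

#: Bioactivity cutoff: 10 μM expressed in nM.
DEFAULT_THRESHOLD_NM = 10_000.0

#: Endpoints admitted by default. IC50 is excluded (configurable): the
#: inclusion criterion names inhibition constant/potency (Ki), dissociation
#: constant (Kd) and median effective concentration (EC50).
DEFAULT_ENDPOINTS = ("Ki", "Kd", "EC50")

_NM_UNITS = {"nm"}
_UM_UNITS = {"um", "µm", "μm", "micromolar"}


class MissingActivityError(ValueError):
    """No bioactivity measurement present for a record."""


def to_nanomolar(value: float, unit: str) -> float:
    """Convert one activity value to nM. μM values are multiplied by 1000."""
    u = str(unit).strip().lower()
    if u in _NM_UNITS:
        return float(value)
    if u in _UM_UNITS:
        return float(value) * 1000.0
    raise ValueError(f"malformed activity unit {unit!r}")


def normalize_activity(activities) -> float:
    """Best (minimum) activity in nM across a record's endpoints.

    Parameters
    ----------
    activities:
        Mapping ``endpoint -> (value, unit)`` or iterable of
        ``(endpoint, value, unit)`` triples.

    Raises
    ------
    MissingActivityError
        If no measurement is present.
    """
    if hasattr(activities, "items"):
        triples = [(e, v, u) for e, (v, u) in activities.items()]
    else:
        triples = list(activities)
    if not triples:
        raise MissingActivityError("record carries no activity measurement")
    return min(to_nanomolar(v, u) for _, v, u in triples)


def _clean_accession(raw: str) -> tuple[str | None, str | None]:
    """Collapse isoform suffixes; reject multi-accession entries.

    Returns (primary_accession, error_reason)."""
    acc = str(raw).strip()
    if not acc or acc.lower() == "nan":
        return None, "missing_accession"
    if any(sep in acc for sep in (";", ",", "|")) or " " in acc:
        return None, "non_unique_accession"
    # Isoform suffix (e.g. P30556-2) maps to the primary accession.
    return acc.split("-")[0], None


def filter_interactions(
    records: pd.DataFrame,
    threshold_nm: float = DEFAULT_THRESHOLD_NM,
    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion criteria to a raw interaction table.

    A (drug, target) pair is kept iff the organism is Homo sapiens, the
    review status is ``reviewed``, the accession resolves to a single
    primary accession, and its best activity over the admitted endpoints
    is <= ``threshold_nm`` (boundary inclusive). Output is deduplicated on
    (drug_id, accession) with the minimum activity retained.

    Returns
    -------
    (edges, dropped):
        ``edges`` has columns drug_id, accession, gene_symbol,
        best_activity_nM; ``dropped`` records every excluded input row with
        a ``reason`` column (malformed rows become error records rather
        than aborting the run).
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    records = records.copy()
    for col in INTERACTION_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"interaction table missing column {col!r}")

    kept_rows: list[dict] = []
    dropped: list[dict] = []
    for idx, row in records.iterrows():
        reason = None
        acc, acc_err = _clean_accession(row["accession"])
        organism = str(row["organism"]).strip().lower()
        status = str(row["review_status"]).strip().lower()
        if acc_err:
            reason = acc_err
        elif organism != "homo sapiens":
            reason = "non_human_organism"
        elif status != "reviewed":
            reason = "not_reviewed"
        elif str(row["endpoint"]) not in endpoints:
            reason = "endpoint_not_admitted"
        else:
            try:
                value = float(row["value"])
                if not value > 0 or math.isnan(value):
                    reason = "non_positive_activity"
                else:
                    activity_nm = to_nanomolar(value, row["unit"])
            except (TypeError, ValueError):
                reason = "malformed_activity"
        if reason is not None:
            dropped.append({"row": idx, "reason": reason, **row.to_dict()})
            continue
        kept_rows.append(
            {
                "row": idx,
                "drug_id": row["drug_id"],
                "accession": acc,
                "gene_symbol": str(row["gene_symbol"]).strip(),
                "activity_nM": activity_nm,
            }
        )

    if not kept_rows:
        edges = pd.DataFrame(
            columns=["drug_id", "accession", "gene_symbol", "best_activity_nM"]
        )
        return edges, pd.DataFrame(dropped)

    df = pd.DataFrame(kept_rows)
    # One gene symbol per accession: conflicting symbols become error records.
    sym_counts = df.groupby("accession")["gene_symbol"].nunique()
    conflicted = set(sym_counts[sym_counts > 1].index)
    if conflicted:
        bad = df["accession"].isin(conflicted)
        for _, row in df[bad].iterrows():
            dropped.append(
                {"row": row["row"], "reason": "conflicting_gene_symbol", **row.to_dict()}
            )
        df = df[~bad]

    grouped = (
        df.groupby(["drug_id", "accession"], as_index=False)
        .agg(gene_symbol=("gene_symbol", "first"), best_activity_nM=("activity_nM", "min"))
    )
    above = grouped["best_activity_nM"] > threshold_nm
    for _, row in grouped[above].iterrows():
        dropped.append({"row": None, "reason": "activity_above_threshold", **row.to_dict()})
    edges = (
        grouped[~above]
        .sort_values(["drug_id", "accession"])
        .reset_index(drop=True)
    )
    return edges, pd.DataFrame(dropped)


@dataclass
class GroupNetwork:
    """Bipartite drug : tc-gene network of one structural group."""

    group: str
    graph: nx.Graph
    drug_nodes: frozenset
    gene_nodes: frozenset

    @property
    def tc_gene_set(self) -> frozenset:
        """Unique target-coding genes of the group (projection of edges)."""
        return self.gene_nodes

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (u, v) if self.graph.nodes[u]["kind"] == "drug" else (v, u)
            for u, v in self.graph.edges
        }


def build_group_networks(
    edges: pd.DataFrame, assignments: pd.DataFrame
) -> dict[str, GroupNetwork]:
    """Split validated edges into per-group bipartite networks.

    Drugs assigned to a group but lacking surviving edges are retained as
    isolated drug nodes (they count in the tc-genes/molecules denominator).
    Drugs labelled ``unassigned`` are excluded.
    """
    group_of = dict(zip(assignments["drug_id"], assignments["group"]))
    networks: dict[str, GroupNetwork] = {}
    for g in GROUPS:
        graph = nx.Graph()
        drugs = [d for d, grp in group_of.items() if grp == g]
        graph.add_nodes_from(drugs, bipartite=0, kind="drug")
        genes: set[str] = set()
        if len(edges):
            sub = edges[edges["drug_id"].isin(drugs)]
            for _, row in sub.iterrows():
                gene = row["gene_symbol"]
                genes.add(gene)
                graph.add_node(gene, bipartite=1, kind="gene")
                graph.add_edge(row["drug_id"], gene)
        networks[g] = GroupNetwork(
            group=g,
            graph=graph,
            drug_nodes=frozenset(drugs),
            gene_nodes=frozenset(genes),
        )
    return networks


def degree_summary(network: GroupNetwork) -> dict:
    """Per-drug gene counts, per-gene drug counts and the tc-genes/molecules ratio.

    The ratio |tc_gene_set| / |drug_nodes| counts isolated drugs in the
    denominator; with zero drugs it is undefined and reported as ``None``.
    """
    g = network.graph
    per_drug = {d: g.degree(d) for d in sorted(network.drug_nodes)}
    per_gene = {t: g.degree(t) for t in sorted(network.gene_nodes)}
    n_drugs = len(network.drug_nodes)
    n_genes = len(network.gene_nodes)
    ratio = n_genes / n_drugs if n_drugs else None
    return {
        "group": network.group,
        "n_drugs": n_drugs,
        "n_genes": n_genes,
        "ratio": ratio,
        "per_drug": per_drug,
        "per_gene": per_gene,
    }


def export_network(network: GroupNetwork, path, fmt: str = "sif") -> None:
    """Write a network in a Cytoscape-consumable plain-text format.

    ``sif`` writes ``drug<TAB>interacts<TAB>gene`` lines; ``graphml``
    carries a node ``kind`` attribute; ``tsv`` is a two-column edge list
    with header. Round-tripping any format returns the identical edge set.
    """
    path = str(path)
    edge_list = sorted(network.edges)
    if fmt == "sif":
        with open(path, "w") as fh:
            for drug, gene in edge_list:
                fh.write(f"{drug}\tinteracts\t{gene}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("drug_id\tgene_symbol\n")
            for drug, gene in edge_list:
                fh.write(f"{drug}\t{gene}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def load_edge_set(path, fmt: str = "sif") -> set[tuple[str, str]]:
    """Read back an exported network as a set of (drug, gene) edges."""
    path = str(path)
    if fmt == "sif":
        edges = set()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    edges.add((parts[0], parts[2]))
        return edges
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return {
            (u, v) if g.nodes[u].get("kind") == "drug" else (v, u)
            for u, v in g.edges
        }
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        return set(zip(df["drug_id"], df["gene_symbol"]))
    raise ValueError(f"unknown export format {fmt!r}")
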