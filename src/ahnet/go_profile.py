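"""GO molecular-function and cellular-component frequency profiles per group.

Annotations are taken at face value (no ontology-graph propagation): rows
with computationally inferred evidence (IEA, and the no-data code ND) are
excluded, exact duplicate (gene, aspect, term) triples are collapsed, and
each term's frequency of occurrence (FOc) in a group is the number of the
group's tc-genes carrying it. Terms with FOc of at least three are retained
for evaluation, except in g1 — the smallest group — where an FOc of two is
acceptable. Cellular-component profiles drop ubiquitous membrane terms
before normalising to a proportion, since those are common to essentially
all drug targets and carry no group-specific signal.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "DEFAULT_EXCLUDED_EVIDENCE",
    "DEFAULT_GENERIC_CC",
    "DEFAULT_FOC_THRESHOLDS",
    "filter_annotations",
    "deduplicate",
    "foc_table",
    "select_terms",
    "cc_distribution",
]

ANNOTATION_COLUMNS = ("gene_symbol", "aspect", "term_id", "term_name", "evidence_code")

#: Evidence codes treated as computationally inferred / uninformative.
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA", "ND"})

#: Generic cellular components excluded before CC proportions are formed.
DEFAULT_GENERIC_CC = frozenset(
    {"plasma membrane", "integral component of plasma membrane", "membrane"}
)

#: Retention cutoffs: FOc >= 3 generally, >= 2 for the smallest group g1.
DEFAULT_FOC_THRESHOLDS = {"default": 3, "g1": 2}

_ASPECTS = {"MF", "CC"}


def filter_annotations(
    annotations: pd.DataFrame,
    excluded_codes=DEFAULT_EXCLUDED_EVIDENCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with excluded evidence codes; flag unknown aspects.

    Returns ``(kept, errors)``; rows whose aspect is not MF/CC become error
    records rather than aborting the run.
    """
    annotations = annotations.copy()
    bad_aspect = ~annotations["aspect"].isin(_ASPECTS)
    errors = annotations[bad_aspect].assign(reason="unknown_aspect")
    kept = annotations[~bad_aspect]
    kept = kept[~kept["evidence_code"].isin(set(excluded_codes))]
    return kept.reset_index(drop=True), errors.reset_index(drop=True)


def deduplicate(annotations: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique (gene, aspect, term) rows; idempotent.

    The same triple supported by several evidence codes counts once; only
    exact-triple redundancy is removed (no near-synonym merging).
    """
    return (
        annotations.drop_duplicates(subset=["gene_symbol", "aspect", "term_id"])
        .reset_index(drop=True)
    )


def foc_table(group_gene_set, annotations: pd.DataFrame, aspect: str) -> pd.DataFrame:
    """Frequency of occurrence of each term within one group's gene set.

    FOc counts distinct annotated genes, not annotation instances; genes
    outside the group are ignored. Returns columns term_id, term_name, foc
    sorted by descending FOc then term name.
    """
    if aspect not in _ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    genes = set(group_gene_set)
    sub = annotations[
        (annotations["aspect"] == aspect) & annotations["gene_symbol"].isin(genes)
    ]
    sub = deduplicate(sub)
    if sub.empty:
        return pd.DataFrame(columns=["term_id", "term_name", "foc"])
    out = (
        sub.groupby(["term_id", "term_name"], as_index=False)
        .agg(foc=("gene_symbol", "nunique"))
        .sort_values(["foc", "term_name"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def select_terms(
    foc: pd.DataFrame, group: str, thresholds: dict | None = None
) -> pd.DataFrame:
    """Retain terms meeting the group's FOc cutoff.

    Output is monotone in the threshold: lowering it can only add terms.
    """
    thresholds = dict(DEFAULT_FOC_THRESHOLDS if thresholds is None else thresholds)
    cutoff = thresholds.get(group, thresholds.get("default", 3))
    return foc[foc["foc"] >= cutoff].reset_index(drop=True)


def cc_distribution(
    group_gene_set,
    annotations: pd.DataFrame,
    exclusion_list=DEFAULT_GENERIC_CC,
) -> pd.Series:
    """Proportion of CC annotations per term, after generic-term exclusion.

    Terms whose name is in ``exclusion_list`` (case-insensitive) are omitted
    before normalisation; remaining proportions sum to 1. An empty result
    (no informative CC annotations) is returned as an empty Series.
    """
    excluded = {t.lower() for t in exclusion_list}
    foc = foc_table(group_gene_set, annotations, "CC")
    foc = foc[~foc["term_name"].str.lower().isin(excluded)]
    if foc.empty or foc["foc"].sum() == 0:
        return pd.Series(dtype=float)
    props = foc.set_index("term_name")["foc"] / foc["foc"].sum()
    return props.astype(float)
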