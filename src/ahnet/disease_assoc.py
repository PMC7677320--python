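"""Gene–disease association filtering, scoring and per-group ranking.

Associations follow the Open-Targets evidence model: each (gene, health
condition) record carries a GWAS-derived relevance p-value and three factors
in [0, 1] — F, the relative occurrence of the gene–disease evidence; S, the
strength of the effect; and C, the confidence in the observation — whose
product is the association score s = F·S·C. Records are filtered at
p ≤ 2.0e-9 (the loosest cutoff at which every structural group retains at
least one association), conditions are ranked per group by their minimum
p-value across the group's genes, and the top-20 conditions are profiled by
how many of the group's genes support them. The score s is reported but
never used for ranking; ranking is by p-value only.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ASSOCIATION_COLUMNS",
    "DEFAULT_P_THRESHOLD",
    "association_score",
    "filter_associations",
    "derive_p_threshold",
    "top_conditions",
    "condition_gene_counts",
    "common_gene_condition_pct",
]

ASSOCIATION_COLUMNS = (
    "gene_symbol",
    "disease_id",
    "disease_name",
    "p_value",
    "F",
    "S",
    "C",
)

#: Relevance cutoff used throughout the study.
DEFAULT_P_THRESHOLD = 2.0e-9


def association_score(F: float, S: float, C: float) -> float:
    """Association score s = F·S·C; each factor must lie in [0, 1]."""
    for name, v in (("F", F), ("S", S), ("C", C)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"factor {name}={v!r} outside [0, 1]")
    return F * S * C


def filter_associations(
    associations: pd.DataFrame, p_threshold: float = DEFAULT_P_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep associations with p_value <= p_threshold (boundary inclusive).

    Non-positive p-values become error records. The returned kept table
    gains a ``score`` column (s = F·S·C). Idempotent and monotone in the
    threshold.
    """
    associations = associations.copy()
    bad = ~(associations["p_value"] > 0)
    errors = associations[bad].assign(reason="non_positive_p_value")
    ok = associations[~bad]
    kept = ok[ok["p_value"] <= p_threshold].reset_index(drop=True)
    if {"F", "S", "C"}.issubset(kept.columns):
        kept = kept.assign(score=kept["F"] * kept["S"] * kept["C"])
    return kept, errors.reset_index(drop=True)


def derive_p_threshold(per_group_associations: dict[str, pd.DataFrame]) -> float:
    """Loosest cutoff at which every group retains at least one association.

    Computed as the maximum over groups of the within-group minimum p-value.
    The pipeline default remains an explicit threshold (2.0e-9); this
    derivation documents where such a value comes from.
    """
    minima = []
    for group, df in per_group_associations.items():
        if df is None or len(df) == 0:
            raise ValueError(f"group {group!r} has no associations")
        minima.append(float(df["p_value"].min()))
    return max(minima)


def _condition_key(df: pd.DataFrame) -> pd.Series:
    """Disease identity: keyed on disease_id when present, else disease_name."""
    key = df["disease_id"].astype("string")
    missing = key.isna() | (key.str.strip() == "")
    return key.mask(missing, df["disease_name"]).astype(str)


def top_conditions(group_associations: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k health conditions of a group by minimum p-value.

    Per condition, takes the minimum p over the group's genes and the count
    of distinct supporting genes; sorts ascending by p with alphabetical
    disease-name tie-break; truncates to ``k``. Stable: associations with p
    above all retained minima never change the ranking.
    """
    if group_associations.empty:
        return pd.DataFrame(columns=["disease_id", "disease_name", "min_p", "n_genes"])
    df = group_associations.assign(_key=_condition_key(group_associations))
    out = (
        df.groupby("_key", as_index=False)
        .agg(
            disease_id=("disease_id", "first"),
            disease_name=("disease_name", "first"),
            min_p=("p_value", "min"),
            n_genes=("gene_symbol", "nunique"),
        )
        .sort_values(["min_p", "disease_name"], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
        .drop(columns="_key")
    )
    return out


def condition_gene_counts(
    group_associations: pd.DataFrame, conditions=None
) -> pd.Series:
    """Distinct group genes associated with each condition.

    ``conditions`` (names or ids) restricts and orders the output; absent
    conditions count 0.
    """
    if group_associations.empty:
        counts = pd.Series(dtype=int)
    else:
        df = group_associations.assign(_key=_condition_key(group_associations))
        by_id = df.groupby("_key")["gene_symbol"].nunique()
        by_name = df.groupby("disease_name")["gene_symbol"].nunique()
        counts = by_id.combine_first(by_name)
    if conditions is None:
        return counts.astype(int)
    return pd.Series(
        {c: int(counts.get(c, 0)) for c in conditions}, dtype=int
    )


def common_gene_condition_pct(
    common_gene_set, associations: pd.DataFrame, conditions=None
) -> pd.Series:
    """Percentage of a common gene set associated with each condition.

    100 · (number of common genes with a retained association to the
    condition) / |common set|. Raises on an empty common set.
    """
    common = set(common_gene_set)
    if not common:
        raise ValueError("common gene set is empty")
    sub = associations[associations["gene_symbol"].isin(common)]
    counts = condition_gene_counts(sub, conditions)
    return (100.0 * counts / len(common)).astype(float)
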