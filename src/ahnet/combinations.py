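"""Clinically validated drug–drug combination analysis.

Combination lists arrive as free-text generic-name pairs assembled from
clinical sources. Names are canonicalized (case-folding, salt-suffix
stripping, MeSH-style synonym mapping), pairs are deduplicated as unordered
pairs, and pairs whose drugs lack experimentally validated targets are
excluded. On the clean pair list the module computes per-drug partner
statistics, partner-set overlap between two drugs, the distribution of
pairs over structural-group pairs with the group trend ordering
(e.g. g2 > g6 > g1 > g3 = g4 = g5), and per-pair shared-target counts —
the observation being that clinically successful combinations tend to
bind disjoint target sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .overlap_stats import jaccard_percent

__all__ = [
    "load_salt_suffixes",
    "load_name_map",
    "standardize_names",
    "standardize_name",
    "load_combinations",
    "partner_stats",
    "partner_overlap_pct",
    "group_pair_distribution",
    "GroupPairDistribution",
    "pair_target_overlap",
]


def load_salt_suffixes() -> frozenset[str]:
    """Salt/hydrate suffixes from the packaged (editable) resource file."""
    text = resources.files("ahnet").joinpath("data/salt_suffixes.txt").read_text()
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_name_map(path) -> dict[str, str]:
    """Load a raw→canonical name map from a two-column TSV (raw, canonical)."""
    df = pd.read_csv(path, sep="\t")
    raw_col, canon_col = df.columns[:2]
    return {
        str(r).strip().casefold(): str(c).strip().casefold()
        for r, c in zip(df[raw_col], df[canon_col])
    }


def standardize_name(
    name: str, name_map: dict[str, str] | None = None, salts=None
) -> tuple[str, bool]:
    """Canonicalize one generic drug name.

    Case-folds, strips whitespace and trailing salt/hydrate suffixes, then
    applies the synonym map. Returns ``(canonical, mapped)`` where
    ``mapped`` is False for names that pass through unmapped (flagged, not
    dropped).
    """
    if name is None or str(name).strip() == "":
        raise ValueError("empty drug name")
    salts = load_salt_suffixes() if salts is None else salts
    tokens = str(name).strip().casefold().split()
    while len(tokens) > 1 and tokens[-1] in salts:
        tokens.pop()
    cleaned = " ".join(tokens)
    if name_map and cleaned in name_map:
        return name_map[cleaned], True
    return cleaned, name_map is None or cleaned in set(name_map.values())


def standardize_names(
    names, name_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Canonicalize a sequence of names; returns raw/canonical/mapped columns."""
    salts = load_salt_suffixes()
    rows = []
    for raw in names:
        canonical, mapped = standardize_name(raw, name_map, salts)
        rows.append({"raw": raw, "canonical": canonical, "mapped": mapped})
    return pd.DataFrame(rows, columns=["raw", "canonical", "mapped"])


@dataclass
class CombinationLoad:
    """Deduplicated pair list plus exclusion report."""

    pairs: list[tuple[str, str]]
    excluded: list[dict] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)


def load_combinations(
    pair_table: pd.DataFrame,
    name_map: dict[str, str] | None = None,
    validated_drugs: set[str] | None = None,
) -> CombinationLoad:
    """Canonicalize and deduplicate a two-column combination table.

    Pairs are unordered — (a, b) ≡ (b, a) — and stored in lexicographic
    canonical order. Self-pairs become error records; pairs involving a
    drug without experimentally validated targets (when ``validated_drugs``
    is given) are excluded with a report entry, never dropped silently.
    """
    salts = load_salt_suffixes()
    col_a, col_b = pair_table.columns[:2]
    seen: set[tuple[str, str]] = set()
    out = CombinationLoad(pairs=[])
    for idx, row in pair_table.iterrows():
        try:
            a, _ = standardize_name(row[col_a], name_map, salts)
            b, _ = standardize_name(row[col_b], name_map, salts)
        except ValueError as exc:
            out.errors.append({"row": idx, "error": str(exc)})
            continue
        if a == b:
            out.errors.append({"row": idx, "error": f"self-pair {a!r}"})
            continue
        pair = (min(a, b), max(a, b))
        if pair in seen:
            continue
        seen.add(pair)
        if validated_drugs is not None:
            missing = [d for d in pair if d not in validated_drugs]
            if missing:
                out.excluded.append(
                    {"pair": pair, "reason": "no_validated_target", "drugs": missing}
                )
                continue
        out.pairs.append(pair)
    return out


def partner_stats(pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-drug combination count, percent of all pairs, and partner set.

    The handshake identity holds: counts sum to 2·|pairs|.
    """
    partners: dict[str, set[str]] = {}
    for a, b in pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    n = len(pairs)
    counts = Counter()
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    rows = [
        {
            "drug": d,
            "n_pairs": counts[d],
            "pct_of_pairs": 100.0 * counts[d] / n if n else 0.0,
            "partners": tuple(sorted(partners[d])),
        }
        for d in sorted(partners)
    ]
    return (
        pd.DataFrame(rows, columns=["drug", "n_pairs", "pct_of_pairs", "partners"])
        .sort_values(["n_pairs", "drug"], ascending=[False, True])
        .reset_index(drop=True)
    )


def partner_overlap_pct(
    pairs: list[tuple[str, str]], a: str, b: str, include_each_other: bool = True
) -> float:
    """Jaccard percentage of two drugs' combination-partner sets.

    With ``include_each_other`` (default) and the two drugs themselves
    paired, each drug is added to the shared set — so being combination
    partners counts toward overlap. Both readings are computable via the
    flag.
    """
    partners: dict[str, set[str]] = {}
    for x, y in pairs:
        partners.setdefault(x, set()).add(y)
        partners.setdefault(y, set()).add(x)
    for d in (a, b):
        if d not in partners:
            raise ValueError(f"drug {d!r} absent from pair list")
    pa, pb = partners[a], partners[b]
    shared = pa & pb
    union = pa | pb
    if include_each_other and (min(a, b), max(a, b)) in {
        (min(x, y), max(x, y)) for x, y in pairs
    }:
        shared = shared | {a, b}
        union = union | {a, b}
    if not union:
        raise ValueError("both partner sets empty")
    return 100.0 * len(shared) / len(union)


@dataclass
class GroupPairDistribution:
    """Distribution of combinations over structural-group pairs."""

    pair_counts: dict[tuple[str, str], int]
    within_group_pct: dict[str, float]
    group_involvement: dict[str, int]  # pairs involving >= 1 member of the group
    trend: list[list[str]]  # tie-classes, descending involvement
    excluded: list[dict] = field(default_factory=list)

    @property
    def trend_str(self) -> str:
        return " > ".join(" = ".join(tie) for tie in self.trend)


def group_pair_distribution(
    pairs: list[tuple[str, str]], assignments: dict[str, str]
) -> GroupPairDistribution:
    """Count pairs per unordered group pair and derive the group trend.

    ``assignments`` maps canonical drug name → group label. Pairs with an
    unassigned/unknown drug are excluded with a warning entry. The trend
    orders groups by the number of pairs involving at least one member,
    ties rendered as "=" classes (e.g. ``g3 = g4 = g5``).
    """
    counts: Counter = Counter()
    involvement: Counter = Counter()
    excluded: list[dict] = []
    n_used = 0
    for a, b in pairs:
        ga, gb = assignments.get(a), assignments.get(b)
        if ga in (None, "unassigned") or gb in (None, "unassigned"):
            excluded.append({"pair": (a, b), "reason": "unassigned_drug"})
            continue
        counts[(min(ga, gb), max(ga, gb))] += 1
        for g in {ga, gb}:
            involvement[g] += 1
        n_used += 1
    groups = sorted(set(assignments.values()) - {"unassigned"})
    within = {
        g: 100.0 * counts.get((g, g), 0) / n_used if n_used else 0.0 for g in groups
    }
    inv = {g: involvement.get(g, 0) for g in groups}
    trend: list[list[str]] = []
    for g in sorted(groups, key=lambda g: (-inv[g], g)):
        if trend and inv[trend[-1][0]] == inv[g]:
            trend[-1].append(g)
        else:
            trend.append([g])
    return GroupPairDistribution(
        pair_counts=dict(counts),
        within_group_pct=within,
        group_involvement=inv,
        trend=trend,
        excluded=excluded,
    )


def pair_target_overlap(
    pairs: list[tuple[str, str]], targets_by_drug: dict[str, set[str]]
) -> pd.DataFrame:
    """Shared-target count and disjointness flag per combination pair.

    Pairs with a drug lacking target data are flagged ``unknown`` instead
    of guessed. The companion cohort-level statistic — the fraction of
    known pairs binding fully disjoint target sets — is
    ``df[~df.unknown].disjoint.mean()``.
    """
    rows = []
    for a, b in pairs:
        ta, tb = targets_by_drug.get(a), targets_by_drug.get(b)
        unknown = ta is None or tb is None
        shared = 0 if unknown else len(set(ta) & set(tb))
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "shared_targets": shared,
                "disjoint": (not unknown) and shared == 0,
                "unknown": unknown,
            }
        )
    return pd.DataFrame(
        rows, columns=["drug_a", "drug_b", "shared_targets", "disjoint", "unknown"]
    )
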