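"""Ring-pattern classification of small molecules into six structural groups.

Anti-hypertensive drugs fall into six structural groups (g1..g6) defined
purely on the multiset of ring sizes of a molecule, counted under the
smallest-set-of-smallest-rings (SSSR) convention — each smallest ring counts
once, fused systems contribute one ring per smallest ring:

* **g1** — four to six rings, of which two or three are five-membered
  (e.g. phenyl-imidazole/tetrazole sartans such as losartan).
* **g2** — two or three rings, all six-membered (the most populated group,
  e.g. dihydropyridine calcium-channel blockers).
* **g3** — exactly two rings, at least one five-membered.
* **g4** — four to six rings with ratio total/six-membered < 1.4.
* **g5** — exactly three rings: two six-membered plus one five- or
  seven-membered.
* **g6** — monocyclic molecules.

The rules are mutually exclusive (proved exhaustively in the test suite);
profiles matched by none are labelled ``unassigned`` rather than forced to
a nearest group, so classification error stays visible.

The module consumes ring-size multisets directly, so no chemistry toolkit is
required; :func:`ring_sizes_from_smiles` is an optional rdkit-backed adapter
for callers who start from structures.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GROUPS",
    "RULE_ORDER",
    "InvalidRingError",
    "RingProfile",
    "make_ring_profile",
    "parse_ring_sizes",
    "ring_sizes_from_smiles",
    "assign_group",
    "matching_groups",
    "classify_cohort",
]

#: Canonical group order used throughout the package.
GROUPS: tuple[str, ...] = ("g1", "g2", "g3", "g4", "g5", "g6")

#: Fixed rule evaluation order. Irrelevant given rule disjointness (asserted
#: in tests), but fixed for reproducibility.
RULE_ORDER: tuple[str, ...] = ("g6", "g3", "g2", "g5", "g1", "g4")

UNASSIGNED = "unassigned"


class InvalidRingError(ValueError):
    """A ring size below three was supplied (no such ring exists)."""


@dataclass(frozen=True)
class RingProfile:
    """Multiset of ring sizes of one molecule plus derived counts.

    Attributes
    ----------
    ring_sizes:
        Sorted tuple of ring member counts (SSSR rings), each >= 3.
    """

    ring_sizes: tuple[int, ...]

    @property
    def n_total(self) -> int:
        """Total number of rings."""
        return len(self.ring_sizes)

    @property
    def n5(self) -> int:
        """Number of five-membered rings."""
        return sum(1 for s in self.ring_sizes if s == 5)

    @property
    def n6(self) -> int:
        """Number of six-membered rings."""
        return sum(1 for s in self.ring_sizes if s == 6)

    @property
    def n7(self) -> int:
        """Number of seven-membered rings."""
        return sum(1 for s in self.ring_sizes if s == 7)


def make_ring_profile(ring_sizes: Iterable[int]) -> RingProfile:
    """Build a :class:`RingProfile` from an iterable of ring sizes.

    Parameters
    ----------
    ring_sizes:
        Ring member counts; the empty iterable denotes an acyclic molecule.

    Raises
    ------
    InvalidRingError
        If any size is below 3 (or not an integer).
    """
    sizes = []
    for s in ring_sizes:
        n = int(s)
        if n != s or n < 3:
            raise InvalidRingError(f"invalid ring size {s!r}: rings have >= 3 members")
        sizes.append(n)
    return RingProfile(tuple(sorted(sizes)))


def parse_ring_sizes(text: str) -> RingProfile:
    """Parse a comma-separated ring-size string (e.g. ``"5,5,6,6"``).

    Empty or whitespace-only strings denote an acyclic molecule.
    """
    if text is None or str(text).strip() == "":
        return make_ring_profile(())
    parts = [p for p in str(text).replace(";", ",").split(",") if p.strip()]
    try:
        sizes = [int(p) for p in parts]
    except ValueError as exc:
        raise InvalidRingError(f"unparseable ring sizes {text!r}") from exc
    return make_ring_profile(sizes)


def ring_sizes_from_smiles(smiles: str) -> RingProfile:
    """Perceive SSSR ring sizes from a SMILES string (requires rdkit).

    Optional adapter: the rest of the package never imports rdkit.
    """
    from rdkit import Chem  # deferred: chemistry support is optional

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidRingError(f"unparseable SMILES {smiles!r}")
    info = mol.GetRingInfo()
    return make_ring_profile(len(ring) for ring in info.AtomRings())


# -- group rules -------------------------------------------------------------

def _rule_g1(p: RingProfile) -> bool:
    return 4 <= p.n_total <= 6 and p.n5 in (2, 3)


def _rule_g2(p: RingProfile) -> bool:
    return p.n_total in (2, 3) and p.n6 == p.n_total


def _rule_g3(p: RingProfile) -> bool:
    return p.n_total == 2 and p.n5 >= 1


def _rule_g4(p: RingProfile) -> bool:
    # Ratio undefined when no six-membered ring: rule fails, not a zero division.
    return 4 <= p.n_total <= 6 and p.n6 > 0 and p.n_total / p.n6 < 1.4


def _rule_g5(p: RingProfile) -> bool:
    return p.n_total == 3 and p.n6 == 2 and (p.n5 == 1 or p.n7 == 1)


def _rule_g6(p: RingProfile) -> bool:
    return p.n_total == 1


_RULES = {
    "g1": _rule_g1,
    "g2": _rule_g2,
    "g3": _rule_g3,
    "g4": _rule_g4,
    "g5": _rule_g5,
    "g6": _rule_g6,
}


def matching_groups(profile: RingProfile) -> list[str]:
    """All group rules matched by ``profile``, in canonical group order.

    Exposed mainly so disjointness (at most one match) can be checked
    exhaustively.
    """
    return [g for g in GROUPS if _RULES[g](profile)]


def assign_group(profile: RingProfile) -> str:
    """Assign the unique structural group label, or ``"unassigned"``.

    Deterministic and pure: evaluation follows :data:`RULE_ORDER`, though
    order cannot matter because the six rules are mutually exclusive.
    """
    for g in RULE_ORDER:
        if _RULES[g](profile):
            return g
    return UNASSIGNED


@dataclass
class CohortClassification:
    """Result of classifying a drug cohort."""

    assignments: pd.DataFrame  # columns: drug_id, name, group
    counts: dict[str, int]  # per-group counts (+ "unassigned")
    errors: list[dict] = field(default_factory=list)  # per-row error records

    @property
    def unassigned(self) -> list[str]:
        m = self.assignments
        return list(m.loc[m["group"] == UNASSIGNED, "drug_id"])


def classify_cohort(
    drugs: pd.DataFrame, ring_column: str = "ring_sizes"
) -> CohortClassification:
    """Classify every drug in a cohort table.

    Parameters
    ----------
    drugs:
        Table with at least ``drug_id`` and ``ring_column`` (comma-separated
        ring sizes, or an iterable of ints per row).

    Every drug receives exactly one label; rows whose profile cannot be
    parsed yield a per-row error record instead of aborting the run, and
    are excluded from the assignment table.
    """
    rows: list[dict] = []
    errors: list[dict] = []
    for _, row in drugs.iterrows():
        raw = row.get(ring_column)
        try:
            if isinstance(raw, (str, type(None))) or raw != raw:  # str/None/NaN
                profile = parse_ring_sizes(raw)
            else:
                profile = make_ring_profile(raw)
        except InvalidRingError as exc:
            errors.append({"drug_id": row.get("drug_id"), "error": str(exc)})
            continue
        rows.append(
            {
                "drug_id": row.get("drug_id"),
                "name": row.get("name", row.get("drug_id")),
                "group": assign_group(profile),
            }
        )
    assignments = pd.DataFrame(rows, columns=["drug_id", "name", "group"])
    counts = {g: int((assignments["group"] == g).sum()) for g in GROUPS}
    counts[UNASSIGNED] = int((assignments["group"] == UNASSIGNED).sum())
    return CohortClassification(assignments=assignments, counts=counts, errors=errors)
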