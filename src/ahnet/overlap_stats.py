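"""Pairwise gene-set overlap between structural groups.

The overlap statistic Cg between the tc-gene sets of two groups is the
Jaccard index expressed as a percentage,

    Cg = 100 * n(A ∩ B) / n(A ∪ B),
    n(A ∪ B) = n(A) + n(B) - n(A ∩ B),

rendered as a symmetric 6×6 matrix with a four-level glyph (open /
quarter / half / full circle) per cell for at-a-glance reading, plus a
three-set Venn decomposition for the overlapping groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_grouping import GROUPS

__all__ = [
    "DEFAULT_GLYPH_BINS",
    "UndefinedOverlapError",
    "jaccard_percent",
    "quantize_fill",
    "OverlapMatrix",
    "overlap_matrix",
    "VennTriple",
    "venn_triple",
]

#: Glyph bin edges (percent): open < 12.5 <= quarter < 37.5 <= half < 75 <= full.
#: The four qualitative levels are fixed by the study; the numeric edges are
#: this package's (configurable) choice.
DEFAULT_GLYPH_BINS = (12.5, 37.5, 75.0)

_GLYPHS = ("open", "quarter", "half", "full")


class UndefinedOverlapError(ValueError):
    """Overlap of two empty sets is undefined (not 0 or 100)."""


def jaccard_percent(a, b) -> float:
    """Percentage of common elements: 100·|A∩B| / |A∪B|.

    Uses the inclusion–exclusion union identity
    ``|A∪B| = |A| + |B| - |A∩B]``. Raises :class:`UndefinedOverlapError`
    when both sets are empty.
    """
    a, b = set(a), set(b)
    inter = len(a & b)
    union = len(a) + len(b) - inter
    if union == 0:
        raise UndefinedOverlapError("overlap of two empty sets is undefined")
    return 100.0 * inter / union


def quantize_fill(value: float, bins=DEFAULT_GLYPH_BINS) -> str:
    """Map a percentage to one of four circle-fill glyphs."""
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"percentage {value!r} outside [0, 100]")
    lo, mid, hi = bins
    if value < lo:
        return "open"
    if value < mid:
        return "quarter"
    if value < hi:
        return "half"
    return "full"


@dataclass
class OverlapMatrix:
    """Symmetric matrix of Cg percentages with a glyph rendering.

    Cells where both gene sets are empty hold NaN (undefined) and the glyph
    ``"undefined"``; the diagonal is 100 for non-empty sets.
    """

    groups: tuple[str, ...]
    values: pd.DataFrame
    glyphs: pd.DataFrame


def overlap_matrix(
    gene_sets: dict[str, set], order: tuple[str, ...] = GROUPS, bins=DEFAULT_GLYPH_BINS
) -> OverlapMatrix:
    """Full pairwise Cg matrix over the (possibly empty) group gene sets."""
    order = tuple(order)
    vals = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    glyphs = pd.DataFrame("undefined", index=order, columns=order, dtype=object)
    for i, gx in enumerate(order):
        for gy in order[i:]:
            try:
                c = jaccard_percent(gene_sets.get(gx, set()), gene_sets.get(gy, set()))
            except UndefinedOverlapError:
                continue
            vals.loc[gx, gy] = vals.loc[gy, gx] = c
            glyphs.loc[gx, gy] = glyphs.loc[gy, gx] = quantize_fill(c, bins)
    return OverlapMatrix(groups=order, values=vals, glyphs=glyphs)


@dataclass
class VennTriple:
    """Seven-region decomposition of three gene sets.

    ``counts`` keys: ``a``, ``b``, ``c`` (exclusive regions), ``ab``,
    ``ac``, ``bc`` (pairwise-only) and ``abc`` (triple intersection).
    """

    counts: dict[str, int]
    triple: frozenset

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def venn_triple(a, b, c) -> VennTriple:
    """Region counts of the three-set Venn diagram, plus the triple set."""
    a, b, c = set(a), set(b), set(c)
    abc = a & b & c
    counts = {
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(abc),
    }
    return VennTriple(counts=counts, triple=frozenset(abc))
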