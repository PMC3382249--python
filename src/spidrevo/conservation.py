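"""Alignment similarity and physiochemical conservation statistics.

Built for cysteine-rich egg case protein (ECP/ECPL) comparisons: pairwise %
similarity with gaps treated as missing data, per-column conservation tiers
(strict identity, full physiochemical-category agreement, or >50% majority),
cross-group conservation of shared sites, and conserved-cysteine scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .sequences import GAP, MultipleAlignment

#: Taylor/Venn physiochemical sets, most specific first; the final universal
#: category guarantees every residue is covered.
DEFAULT_CATEGORIES: tuple[tuple[str, frozenset], ...] = (
    ("Proline", frozenset("P")),
    ("Glycine", frozenset("G")),
    ("Negative", frozenset("DE")),
    ("Positive", frozenset("HKR")),
    ("Tiny", frozenset("AGS")),
    ("Aliphatic", frozenset("ILV")),
    ("Aromatic", frozenset("FHWY")),
    ("Charged", frozenset("DEHKR")),
    ("Small", frozenset("ACDGNPSTV")),
    ("Polar", frozenset("CDEHKNQRSTWY")),
    ("Hydrophobic", frozenset("ACFGHIKLMTVWY")),
    ("Any", frozenset("ACDEFGHIKLMNPQRSTVWYX")),
)

TIER_ORDER = {"identical_100": 3, "category_100": 2, "majority_gt50": 1, "none": 0}


@dataclass(frozen=True)
class ResidueCategoryTable:
    """Ordered physiochemical categories, smallest/most specific first."""

    categories: tuple[tuple[str, frozenset], ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("category table may not be empty")
        for name, members in self.categories:
            if not members:
                raise ValueError(f"category {name!r} is empty")
        universe = set().union(*(m for _, m in self.categories))
        if not set("ACDEFGHIKLMNPQRSTVWY") <= universe:
            raise ValueError("table must cover all 20 amino acids")

    def smallest_covering(self, residues: set[str]) -> str | None:
        """Name of the first (most specific) category covering all residues."""
        for name, members in self.categories:
            if residues <= members:
                return name
        return None

    def covering_fraction(self, residues: list[str]) -> tuple[str, float]:
        """Best (category, fraction of residues it covers)."""
        best_name, best_frac = "Any", 0.0
        for name, members in self.categories:
            frac = sum(1 for r in residues if r in members) / len(residues)
            if frac > best_frac:
                best_name, best_frac = name, frac
        return best_name, best_frac


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise % similarity with optional group labels and group means."""

    matrix: pd.DataFrame  # square, symmetric, diagonal 100; NaN = undefined
    groups: dict  # seq id -> group label

    def within_group_mean(self, group: str) -> float:
        ids = [i for i, g in self.groups.items() if g == group]
        vals = [
            self.matrix.loc[a, b]
            for a, b in combinations(ids, 2)
            if not np.isnan(self.matrix.loc[a, b])
        ]
        if not vals:
            raise ValueError(f"no defined pairs within group {group!r}")
        return float(np.mean(vals))

    def between_group_mean(self, group_a: str, group_b: str) -> float:
        ids_a = [i for i, g in self.groups.items() if g == group_a]
        ids_b = [i for i, g in self.groups.items() if g == group_b]
        vals = [
            self.matrix.loc[a, b]
            for a in ids_a
            for b in ids_b
            if not np.isnan(self.matrix.loc[a, b])
        ]
        if not vals:
            raise ValueError(f"no defined pairs between {group_a!r} and {group_b!r}")
        return float(np.mean(vals))


def pairwise_similarity(
    alignment: MultipleAlignment, groups: dict | None = None
) -> SimilarityMatrix:
    """Pairwise % similarity; gaps are treated as missing data.

    Per pair: % of identical columns among columns where both rows are
    non-gap.  A pair sharing zero non-gap columns has undefined similarity
    (NaN in the matrix, skipped by the group means).
    """
    ids = alignment.ids
    mat = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    for rid in ids:
        mat.loc[rid, rid] = 100.0
    for (id_a, row_a), (id_b, row_b) in combinations(alignment.rows, 2):
        cols = matches = 0
        for x, y in zip(row_a, row_b):
            if x == GAP or y == GAP:
                continue
            cols += 1
            matches += x == y
        sim = 100.0 * matches / cols if cols else np.nan
        mat.loc[id_a, id_b] = mat.loc[id_b, id_a] = sim
    return SimilarityMatrix(mat, groups or {i: "all" for i in ids})


def column_conservation(
    alignment: MultipleAlignment, table: ResidueCategoryTable | None = None
) -> list[tuple[str, str | None]]:
    """Per-column conservation tier and the category responsible.

    Tiers, considering only non-gap residues in the column:
    ``identical_100`` (one residue), ``category_100`` (one smallest category
    covers all), ``majority_gt50`` (a residue or category covers >50%), else
    ``none`` (all-gap columns are ``none``).
    """
    table = table or ResidueCategoryTable()
    out: list[tuple[str, str | None]] = []
    for j in range(alignment.length):
        residues = [r for r in alignment.column(j) if r != GAP]
        if not residues:
            out.append(("none", None))
            continue
        distinct = set(residues)
        if len(distinct) == 1:
            out.append(("identical_100", residues[0]))
            continue
        cat = table.smallest_covering(distinct)
        if cat is not None and cat != "Any":
            out.append(("category_100", cat))
            continue
        # majority: a single residue >50%?
        top = max(distinct, key=lambda r: residues.count(r))
        if residues.count(top) / len(residues) > 0.5:
            out.append(("majority_gt50", top))
            continue
        name, frac = table.covering_fraction(residues)
        if frac > 0.5 and name != "Any":
            out.append(("majority_gt50", name))
        else:
            out.append(("none", None))
    return out


def cross_group_conservation(
    alignment: MultipleAlignment,
    group_a: list[str],
    group_b: list[str],
    table: ResidueCategoryTable | None = None,
    min_tier: str = "majority_gt50",
) -> float:
    """% of qualifying sites conserved across two sequence groups.

    Qualifying sites have at least one non-gap residue in each group; a site
    counts as conserved when the pooled-column tier reaches ``min_tier``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    tiers = column_conservation(alignment, table)
    rows_a = [alignment.row(i) for i in group_a]
    rows_b = [alignment.row(i) for i in group_b]
    qualifying = conserved = 0
    for j in range(alignment.length):
        if all(r[j] == GAP for r in rows_a) or all(r[j] == GAP for r in rows_b):
            continue
        qualifying += 1
        if TIER_ORDER[tiers[j][0]] >= TIER_ORDER[min_tier]:
            conserved += 1
    if qualifying == 0:
        raise ValueError("no qualifying sites shared by the two groups")
    return 100.0 * conserved / qualifying


def conservation_table(
    alignment: MultipleAlignment, table: ResidueCategoryTable | None = None
) -> pd.DataFrame:
    """Per-column annotation (BED-like: start, end, tier, category)."""
    tiers = column_conservation(alignment, table)
    return pd.DataFrame(
        {
            "start": range(alignment.length),
            "end": range(1, alignment.length + 1),
            "tier": [t for t, _ in tiers],
            "category": [c for _, c in tiers],
        }
    )


def cysteine_conservation(
    alignment: MultipleAlignment,
) -> tuple[list[int], list[int]]:
    """Columns where cysteine occupies 100% / ≥50% of the non-gap rows."""
    full, half = [], []
    for j in range(alignment.length):
        residues = [r for r in alignment.column(j) if r != GAP]
        if not residues:
            continue
        frac = residues.count("C") / len(residues)
        if frac == 1.0:
            full.append(j)
        if frac >= 0.5 and "C" in residues:
            half.append(j)
    return full, half
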