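"""Amino-acid composition of repeat regions and the Ala/Gly/Ser matrix.

Silk mechanical properties track the composition of the repetitive region,
dominated by alanine, glycine and serine.  This module computes per-sequence
composition profiles over declared region intervals (by default the union of
detected repeat units) and assembles the comparative A/G/S matrix, raw and
column-centered, that underlies heat-map style comparisons across a spidroin
panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequences import BioSequence

Interval = tuple[int, int]


@dataclass(frozen=True)
class CompositionProfile:
    """Residue percentages over a region of one sequence (sum to 100)."""

    seq_id: str
    region: tuple[Interval, ...]
    percent: dict  # residue -> % of counted residues

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")
        if any(v < 0 for v in self.percent.values()):
            raise ValueError("negative percentage")

    def get(self, residue: str) -> float:
        return self.percent.get(residue, 0.0)


def residue_composition(
    seq: BioSequence,
    region: list[Interval] | tuple[Interval, ...] | None = None,
    count_ambiguous: bool = False,
) -> CompositionProfile:
    """Residue composition over ``region`` (whole sequence if omitted).

    ``X`` (and DNA ``N``) are excluded from the denominator unless
    ``count_ambiguous`` is set.
    """
    n = len(seq.residues)
    intervals = tuple(region) if region else ((0, n),)
    residues = []
    for s, e in intervals:
        if not 0 <= s < e <= n:
            raise ValueError(f"region ({s}, {e}) outside sequence bounds [0, {n})")
        residues.extend(seq.residues[s:e])
    if not count_ambiguous:
        ambiguous = "N" if seq.alphabet == "dna" else "X"
        residues = [r for r in residues if r != ambiguous]
    if not residues:
        raise ValueError(f"empty region for {seq.id!r}")
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    total = len(residues)
    percent = {r: 100.0 * c / total for r, c in sorted(counts.items())}
    return CompositionProfile(seq.id, intervals, percent)


@dataclass(frozen=True)
class AGSMatrix:
    """Alanine/glycine/serine percentages across a spidroin panel.

    ``raw`` holds the percentages; ``centered`` subtracts each column's mean
    (the heat-map scale: below-mean vs above-mean).  ``ags_mean`` is the mean
    over sequences of A% + G% + S%.
    """

    raw: pd.DataFrame       # index: seq_id, columns: A, G, S
    centered: pd.DataFrame
    ags_mean: float


def build_ags_matrix(profiles: list[CompositionProfile]) -> AGSMatrix:
    """Assemble the A/G/S comparative matrix from composition profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    raw = pd.DataFrame(
        {res: [p.get(res) for p in profiles] for res in ("A", "G", "S")},
        index=[p.seq_id for p in profiles],
    )
    centered = raw - raw.mean(axis=0)
    ags_mean = float(raw.sum(axis=1).mean())
    return AGSMatrix(raw=raw, centered=centered, ags_mean=ags_mean)
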