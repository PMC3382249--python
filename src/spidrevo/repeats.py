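"""Tandem repeat detection and homogenization statistics for silk proteins.

Spidroin repetitive regions are arrays of long "ensemble" repeat units
(~180 residues in most mygalomorph and mesothele silks) kept nearly identical
by concerted evolution.  This module finds such arrays in protein sequences,
builds 50%-majority-rule consensus units (ambiguities as ``X``), measures
within-array identity, and classifies nucleotide differences from a codon
consensus as synonymous or non-synonymous.

The detector is a self-comparison lag profile: for each candidate period
``p`` it marks positions where the sequence matches itself shifted by ``p``,
finds windows dense in matches, refines the array boundaries, and reduces
each candidate to its primitive (smallest homogenized) period.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align

from .sequences import GAP, BioSequence, MultipleAlignment, translate_codon


@dataclass(frozen=True)
class RepeatArray:
    """A detected tandem array of repeat units within one sequence.

    ``units`` are 0-based half-open intervals in the parent sequence;
    ``aligned_units`` are the unit strings padded onto consensus coordinates;
    ``mean_identity`` is the unweighted mean pairwise % identity among units.
    """

    seq_id: str
    units: tuple[tuple[int, int], ...]
    period: int
    consensus: str
    mean_identity: float
    coverage: float
    aligned_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.units) < 2:
            raise ValueError("a repeat array needs at least 2 units")
        for (s1, e1), (s2, e2) in zip(self.units, self.units[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError("units must be non-overlapping and ascending")
        if not 0 <= self.mean_identity <= 100:
            raise ValueError("mean_identity outside [0, 100]")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def span(self) -> tuple[int, int]:
        return (self.units[0][0], self.units[-1][1])


@dataclass(frozen=True)
class DiffCounts:
    """Synonymous / non-synonymous difference totals against a codon consensus."""

    nonsynonymous: int
    synonymous: int
    alignment_length_nt: int

    def __post_init__(self) -> None:
        if self.nonsynonymous < 0 or self.synonymous < 0:
            raise ValueError("difference counts must be non-negative")
        if self.alignment_length_nt % 3:
            raise ValueError("codon alignment length must be a multiple of 3")

    @property
    def total(self) -> int:
        return self.nonsynonymous + self.synonymous


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def repeat_identity(units: list[str] | tuple[str, ...]) -> float:
    """Mean pairwise % identity among equal-length (gapped) unit strings.

    Per pair, identity = matching columns / columns where at least one member
    is non-gap; columns gapped in both members are excluded.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    if len({len(u) for u in units}) != 1:
        raise ValueError("units must be pre-aligned to equal length")
    idents = []
    for a, b in combinations(units, 2):
        cols = matches = 0
        for x, y in zip(a, b):
            if x == GAP and y == GAP:
                continue
            cols += 1
            if x == y:
                matches += 1
        idents.append(100.0 * matches / cols if cols else 0.0)
    return float(np.mean(idents))


def _plurality_consensus(units: list[str]) -> str:
    """Working consensus: per-column most frequent non-gap symbol (ties: lexical)."""
    out = []
    for col in zip(*units):
        counts: dict[str, int] = {}
        for s in col:
            if s != GAP:
                counts[s] = counts.get(s, 0) + 1
        if not counts:
            continue
        out.append(min(counts, key=lambda s: (-counts[s], s)))
    return "".join(out)


def build_consensus(units: list[str] | tuple[str, ...], majority: float = 0.5) -> str:
    """50%-majority-rule consensus of pre-aligned units; ambiguities become X.

    Per column the most frequent non-gap symbol is emitted iff its frequency
    strictly exceeds ``majority`` of the non-gap count; otherwise ``X``.
    Columns gapped in more than half of the units are dropped.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units for a consensus")
    if len({len(u) for u in units}) != 1:
        raise ValueError("units must be pre-aligned to equal length")
    n = len(units)
    out = []
    for col in zip(*units):
        gaps = sum(1 for s in col if s == GAP)
        if gaps > 0.5 * n:
            continue
        counts: dict[str, int] = {}
        for s in col:
            if s != GAP:
                counts[s] = counts.get(s, 0) + 1
        best = min(counts, key=lambda s: (-counts[s], s))
        nongap = n - gaps
        out.append(best if counts[best] > majority * nongap else "X")
    return "".join(out)


def _align_units_to_consensus(
    units: list[str], consensus: str, aligner: Align.PairwiseAligner
) -> list[str]:
    """Project each unit onto consensus columns via global pairwise alignment."""
    rows = []
    for unit in units:
        aln = aligner.align(consensus, unit)[0]
        row = [GAP] * len(consensus)
        for (cs, ce), (us, ue) in zip(*aln.aligned):
            for k in range(ce - cs):
                row[cs + k] = unit[us + k]
        rows.append("".join(row))
    return rows


def _segment_units(start: int, end: int, period: int) -> list[tuple[int, int]]:
    """Chunk [start, end) into period-length units; keep a final partial ≥ 0.8·p."""
    units = []
    pos = start
    while pos + period <= end:
        units.append((pos, pos + period))
        pos += period
    if end - pos >= 0.8 * period:
        units.append((pos, end))
    return units


def _candidate_regions(
    match: np.ndarray, period: int, min_coverage_run: float, boundary_window: int
) -> list[tuple[int, int]]:
    """Maximal dense-match regions for one lag, with refined boundaries.

    ``match[i]`` says whether position ``i`` equals position ``i + period``.
    Windows of width ``period`` with match fraction ≥ ``min_coverage_run``
    seed a region; boundaries are then snapped to the first/last position
    opening/closing a locally dense (≥ 3/4 within ``boundary_window``) match
    run, which keeps array ends crisp even when the window smears into the
    flanks.
    """
    m = match.astype(float)
    n = len(m)
    if n < period:
        return []
    csum = np.concatenate([[0.0], np.cumsum(m)])
    frac = (csum[period:] - csum[:-period]) / period  # frac[i]: window [i, i+p)
    ok = frac >= min_coverage_run
    regions = []
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            lo, hi = i, min(n, (j - 1) + 2 * period)
            w = boundary_window
            start = next(
                (
                    k
                    for k in range(lo, hi - w + 1)
                    if match[k] and m[k : k + w].mean() >= 0.75
                ),
                None,
            )
            end_idx = next(
                (
                    k
                    for k in range(hi - 1, lo - 1, -1)
                    if match[k] and m[max(0, k - w + 1) : k + 1].mean() >= 0.75
                ),
                None,
            )
            if start is not None and end_idx is not None and end_idx >= start:
                regions.append((start, end_idx + 1 + period))
            i = j
        else:
            i += 1
    return regions


def _array_from_region(
    seq: str,
    seq_id: str,
    start: int,
    end: int,
    period: int,
    aligner: Align.PairwiseAligner,
    refine_rounds: int = 2,
) -> RepeatArray | None:
    units_iv = _segment_units(start, end, period)
    if len(units_iv) < 2:
        return None
    units = [seq[s:e] for s, e in units_iv]
    consensus = _plurality_consensus([u.ljust(period, GAP) for u in units])
    aligned = units
    for _ in range(refine_rounds):
        aligned = _align_units_to_consensus(units, consensus, aligner)
        consensus = _plurality_consensus(aligned)
        # re-project once more only if consensus length changed
        if len(consensus) == len(aligned[0]):
            break
    if len(aligned[0]) != len(consensus):
        aligned = _align_units_to_consensus(units, consensus, aligner)
    identity = repeat_identity(aligned)
    coverage = sum(e - s for s, e in units_iv) / len(seq)
    final_consensus = build_consensus(aligned)
    return RepeatArray(
        seq_id=seq_id,
        units=tuple(units_iv),
        period=len(final_consensus),
        consensus=final_consensus,
        mean_identity=identity,
        coverage=coverage,
        aligned_units=tuple(aligned),
    )


def _chunk_identity(seq: str, start: int, end: int, period: int) -> float:
    """Mean pairwise % identity of period-length chunks, without re-alignment.

    Cheap screen used to pick the primitive period before the expensive
    alignment-refined array is built.
    """
    ivs = _segment_units(start, end, period)
    if len(ivs) < 2:
        return -1.0
    rows = np.full((len(ivs), period), ord(GAP), dtype=np.uint8)
    for r, (s, e) in enumerate(ivs):
        chunk = np.frombuffer(seq[s:e].encode("ascii"), dtype=np.uint8)
        rows[r, : len(chunk)] = chunk
    eq = rows[:, None, :] == rows[None, :, :]
    nongap = (rows[:, None, :] != ord(GAP)) | (rows[None, :, :] != ord(GAP))
    matches = (eq & nongap).sum(axis=2).astype(float)
    cols = nongap.sum(axis=2).astype(float)
    iu = np.triu_indices(len(ivs), k=1)
    with np.errstate(invalid="ignore"):
        per_pair = np.where(cols[iu] > 0, 100.0 * matches[iu] / cols[iu], 0.0)
    return float(per_pair.mean())


def _primitive_period(
    seq: str, start: int, end: int, period: int, min_period: int, margin: float = 2.0
) -> int:
    """Smallest sub-period whose chunk identity stays within ``margin`` points.

    A candidate whose unit is itself a near-perfect tandem of a shorter unit
    is reported at the shorter period — the homogenized unit, not its
    harmonic.
    """
    base_identity = _chunk_identity(seq, start, end, period)
    best = period
    for k in range(2, period // min_period + 1):
        d = round(period / k)
        if d < min_period:
            break
        if _chunk_identity(seq, start, end, d) >= base_identity - margin:
            best = d
    return best


def detect_tandem_repeats(
    seq: BioSequence | str,
    min_period: int = 4,
    max_period: int = 500,
    min_copies: int = 2,
    min_identity: float = 0.7,
    seed_word: int = 4,
    min_coverage_run: float = 0.5,
) -> list[RepeatArray]:
    """Detect tandem repeat arrays in a protein sequence.

    Parameters
    ----------
    seq : BioSequence or str
    min_period, max_period : int
        Candidate unit lengths (residues) to scan.
    min_copies : int
        Minimum number of units per reported array.
    min_identity : float
        Minimum mean pairwise identity among units, as a fraction in [0, 1].
    seed_word : int
        Width of the exact-match seed used when snapping array boundaries
        (small periods use ``min(2 * seed_word, period)``).
    min_coverage_run : float
        Match fraction a period-wide window must reach to seed a candidate.

    Returns
    -------
    list of RepeatArray
        Non-overlapping arrays, in order of position.  Overlapping candidates
        across periods are resolved by greatest coverage, then mean identity,
        then smallest period; each candidate is first reduced to its
        primitive period.
    """
    s = seq.residues if isinstance(seq, BioSequence) else str(seq)
    seq_id = seq.id if isinstance(seq, BioSequence) else "seq"
    n = len(s)
    if n < 2 * min_period:
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    aligner = _aligner()

    candidates: list[RepeatArray] = []
    seen_regions: set[tuple[int, int, int]] = set()
    for p in range(min_period, min(max_period, n // 2) + 1):
        match = arr[:-p] == arr[p:]
        w = min(2 * seed_word, p)
        for lo, hi in _candidate_regions(match, p, min_coverage_run, w):
            # evidence floor: a real array self-matches at its lag well beyond
            # what chance similarity produces in short windows
            if int(match[lo : hi - p].sum()) < 2 * seed_word:
                continue
            d = _primitive_period(s, lo, hi, p, min_period)
            key = (lo, hi, d)
            if key in seen_regions:
                continue
            seen_regions.add(key)
            if _chunk_identity(s, lo, hi, d) < 100 * min_identity - 10:
                continue  # hopeless even before alignment refinement
            array = _array_from_region(s, seq_id, lo, hi, d, aligner)
            if array is None:
                continue
            if array.n_units >= min_copies and array.mean_identity >= 100 * min_identity:
                candidates.append(array)

    # resolve overlaps: greatest coverage, then identity, then smallest period
    candidates.sort(key=lambda a: (-a.coverage, -a.mean_identity, a.period))
    accepted: list[RepeatArray] = []
    for cand in candidates:
        s0, e0 = cand.span
        if all(not (s0 < a.span[1] and a.span[0] < e0) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda a: a.span)
    return accepted


def consensus_dna_from_alignment(codon_alignment: MultipleAlignment) -> str:
    """Per-column plurality nucleotide (ties broken A<C<G<T; all-gap → '-')."""
    out = []
    for j in range(codon_alignment.length):
        counts: dict[str, int] = {}
        for s in codon_alignment.column(j):
            if s != GAP:
                counts[s] = counts.get(s, 0) + 1
        out.append(min(counts, key=lambda s: (-counts[s], s)) if counts else GAP)
    return "".join(out)


def classify_differences(
    codon_unit_alignment: MultipleAlignment, consensus_dna: str | None = None
) -> DiffCounts:
    """Classify per-nucleotide differences from the consensus as syn/non-syn.

    Each nucleotide of each unit that differs from the consensus is
    substituted singly into the consensus codon: if the encoded amino acid
    changes it counts as one non-synonymous difference, otherwise as one
    synonymous difference.  Positions where either the unit or the consensus
    is gapped are skipped (indels are not substitutions).
    """
    length = codon_unit_alignment.length
    if length % 3:
        raise ValueError(f"codon alignment length {length} is not a multiple of 3")
    if consensus_dna is None:
        consensus_dna = consensus_dna_from_alignment(codon_unit_alignment)
    if len(consensus_dna) != length:
        raise ValueError("consensus length does not match alignment length")
    nonsyn = syn = 0
    for _, row in codon_unit_alignment.rows:
        for pos in range(length):
            u, c = row[pos], consensus_dna[pos]
            if u == c or u == GAP or c == GAP:
                continue
            ci = 3 * (pos // 3)
            cons_codon = consensus_dna[ci : ci + 3]
            if GAP in cons_codon:
                raise ValueError(f"frame violation: gap inside consensus codon at {ci}")
            mutated = cons_codon[: pos - ci] + u + cons_codon[pos - ci + 1 :]
            if translate_codon(mutated) != translate_codon(cons_codon):
                nonsyn += 1
            else:
                syn += 1
    return DiffCounts(nonsyn, syn, length)


def detect_subrepeats(consensus: str, k: int = 2) -> tuple[int, float]:
    """Test whether a consensus unit splits into two similar half-units.

    Scans split offsets within ±10% of the midpoint, globally aligns the two
    halves, and returns ``(best_offset, identity_percent)`` for the split
    maximizing identity.  Only ``k=2`` (two subrepeats) is supported.
    """
    if k != 2:
        raise NotImplementedError("only k=2 subrepeats are supported")
    n = len(consensus)
    if n < 2 * k:
        raise ValueError("consensus too short to split")
    aligner = _aligner()
    mid = n // 2
    delta = max(1, round(0.1 * n / 2))
    best = (mid, -1.0)
    for off in range(max(1, mid - delta), min(n - 1, mid + delta) + 1):
        a, b = consensus[:off], consensus[off:]
        aln = aligner.align(a, b)[0]
        matches = sum(
            1
            for (as_, ae), (bs, be) in zip(*aln.aligned)
            for i in range(ae - as_)
            if a[as_ + i] == b[bs + i]
        )
        identity = 100.0 * matches / aln.length
        if identity > best[1]:
            best = (off, identity)
    return best


def arrays_table(arrays: list[RepeatArray]) -> pd.DataFrame:
    """Summary table of detected arrays (write with ``.to_csv(sep='\\t')``)."""
    return pd.DataFrame(
        {
            "seq_id": [a.seq_id for a in arrays],
            "period": [a.period for a in arrays],
            "copies": [a.n_units for a in arrays],
            "start": [a.span[0] for a in arrays],
            "end": [a.span[1] for a in arrays],
            "coverage": [a.coverage for a in arrays],
            "mean_identity": [a.mean_identity for a in arrays],
            "consensus": [a.consensus for a in arrays],
        }
    )


def single_residue_runs(
    consensus: str, min_run: int = 2
) -> list[tuple[str, int, int]]:
    """Maximal single-residue tandem runs: (residue, start, length), length ≥ min_run."""
    runs = []
    i = 0
    while i < len(consensus):
        j = i
        while j < len(consensus) and consensus[j] == consensus[i]:
            j += 1
        if j - i >= min_run and consensus[i] != "X":
            runs.append((consensus[i], i, j - i))
        i = j
    return runs
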