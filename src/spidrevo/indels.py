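"""Simple indel coding of alignment gaps and protein→codon back-translation.

Simple indel coding (Simmons–Ochoterena style) turns each distinct internal
gap run of an alignment into one binary presence/absence character.  A taxon
scores 1 if it has exactly that gap run, ``?`` if its own gap strictly
subsumes the run (so presence/absence is unobservable), and 0 otherwise.
Terminal gap runs mark incomplete sequences, not indel events: by default
they produce no characters and score ``?`` on any character they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .sequences import GAP, BioSequence, MultipleAlignment, SequenceError, translate


@dataclass(frozen=True)
class GapRun:
    """A maximal run of gap columns in one row: [start, end), 0-based."""

    start: int
    end: int
    terminal: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class IndelCharacter:
    """One binary indel character: the column interval of an internal gap run."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad indel interval [{self.start}, {self.end})")


@dataclass
class BinaryMatrix:
    """Taxa × indel characters, states in {'0', '1', '?'}."""

    taxa: list[str]
    characters: list[IndelCharacter]
    states: list[list[str]]  # states[i][j]: taxon i, character j

    def state(self, taxon: str, char: IndelCharacter) -> str:
        return self.states[self.taxa.index(taxon)][self.characters.index(char)]

    def as_dict(self) -> dict[str, dict[tuple[int, int], str]]:
        return {
            t: {(c.start, c.end): self.states[i][j] for j, c in enumerate(self.characters)}
            for i, t in enumerate(self.taxa)
        }


def extract_gap_runs(alignment: MultipleAlignment) -> dict[str, list[GapRun]]:
    """Maximal gap runs per row; runs touching either alignment end are terminal."""
    length = alignment.length
    out: dict[str, list[GapRun]] = {}
    for rid, row in alignment.rows:
        runs: list[GapRun] = []
        i = 0
        while i < length:
            if row[i] == GAP:
                j = i
                while j < length and row[j] == GAP:
                    j += 1
                runs.append(GapRun(i, j, terminal=(i == 0 or j == length)))
                i = j
            else:
                i += 1
        out[rid] = runs
    return out


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    """outer strictly subsumes inner: covers it fully and is longer."""
    return outer[0] <= inner[0] and outer[1] >= inner[1] and outer != inner


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def simple_indel_coding(
    alignment: MultipleAlignment, terminal_gaps: str = "missing"
) -> BinaryMatrix:
    """Code alignment gaps as binary characters by the simple method.

    Parameters
    ----------
    alignment : MultipleAlignment
    terminal_gaps : {"missing", "absent"}
        How a terminal gap scores on characters it overlaps: ``missing`` → ``?``
        (incomplete sequence, the default), ``absent`` → ``0``.
    """
    if terminal_gaps not in ("missing", "absent"):
        raise ValueError(f"terminal_gaps must be 'missing' or 'absent', got {terminal_gaps!r}")
    runs = extract_gap_runs(alignment)
    internal_intervals = sorted(
        {r.interval for rs in runs.values() for r in rs if not r.terminal}
    )
    characters = [IndelCharacter(s, e) for s, e in internal_intervals]
    taxa = alignment.ids
    terminal_state = "?" if terminal_gaps == "missing" else "0"

    states: list[list[str]] = []
    for rid in taxa:
        own = runs[rid]
        own_internal = {r.interval for r in own if not r.terminal}
        own_terminal = [r.interval for r in own if r.terminal]
        row_states: list[str] = []
        for ch in characters:
            iv = (ch.start, ch.end)
            if iv in own_internal:
                state = "1"
            elif any(_contains(r.interval, iv) for r in own if not r.terminal):
                state = "?"
            elif any(_overlaps(t, iv) for t in own_terminal):
                state = terminal_state
            else:
                state = "0"
            row_states.append(state)
        states.append(row_states)
    return BinaryMatrix(list(taxa), characters, states)


def backtranslate(
    protein_alignment: MultipleAlignment, cds: dict[str, BioSequence]
) -> MultipleAlignment:
    """Expand a protein alignment to a codon alignment using the source CDS.

    Each residue column becomes the corresponding codon; gaps become ``---``.
    The CDS must translate exactly to the ungapped protein row (``X`` in the
    protein matches any codon).
    """
    codon_rows: list[tuple[str, str]] = []
    for rid, row in protein_alignment.rows:
        if rid not in cds:
            raise SequenceError(f"no CDS provided for alignment row {rid!r}")
        dna = cds[rid].residues
        protein = row.replace(GAP, "")
        if len(dna) < 3 * len(protein):
            raise SequenceError(
                f"row {rid!r}: CDS has {len(dna)} nt, need {3 * len(protein)}"
            )
        if len(dna) != 3 * len(protein):
            raise SequenceError(
                f"row {rid!r}: CDS length {len(dna)} is not 3×{len(protein)} residues"
            )
        translated = translate(cds[rid]).residues
        for pos, (got, want) in enumerate(zip(translated, protein)):
            if want != "X" and got != want:
                raise SequenceError(
                    f"row {rid!r}: CDS encodes {got!r} but protein row has {want!r} "
                    f"at residue {pos}"
                )
        out = []
        k = 0
        for aa in row:
            if aa == GAP:
                out.append(GAP * 3)
            else:
                out.append(dna[3 * k : 3 * k + 3])
                k += 1
        codon_rows.append((rid, "".join(out)))
    return MultipleAlignment.from_pairs(codon_rows, alphabet="dna")


# ---------------------------------------------------------------------------
# Exports

def write_state_matrix(matrix: BinaryMatrix, path: str | Path) -> None:
    """TSV: one row per taxon, one column per indel character interval."""
    with open(path, "w") as fh:
        header = ["taxon"] + [f"indel_{c.start}_{c.end}" for c in matrix.characters]
        fh.write("\t".join(header) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            fh.write("\t".join([taxon] + matrix.states[i]) + "\n")


def write_nexus(
    alignment: MultipleAlignment, matrix: BinaryMatrix, path: str | Path
) -> None:
    """NEXUS export: DNA/protein characters plus the binary indel partition.

    Uses a MIXED datatype matrix with the indel characters appended as a
    separate standard partition, plus a SETS block naming both partitions.
    """
    n_res = alignment.length
    n_bin = len(matrix.characters)
    dtype = "DNA" if alignment.alphabet == "dna" else "PROTEIN"
    name_w = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={n_res + n_bin};",
        f"    FORMAT DATATYPE=MIXED({dtype}:1-{n_res},STANDARD:{n_res + 1}-{n_res + n_bin})"
        " GAP=- MISSING=?;",
        "    MATRIX",
    ]
    row_by_id = dict(alignment.rows)
    for i, taxon in enumerate(matrix.taxa):
        lines.append(f"    {taxon.ljust(name_w)}{row_by_id[taxon]}{''.join(matrix.states[i])}")
    lines += [
        "    ;",
        "END;",
        "BEGIN SETS;",
        f"    CHARSET residues = 1-{n_res};",
    ]
    if n_bin:
        lines.append(f"    CHARSET indels = {n_res + 1}-{n_res + n_bin};")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")
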