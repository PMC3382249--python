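"""Sequence and alignment containers plus FASTA I/O.

Sequences are plain named residue strings (protein or DNA); alignments are
equal-length gapped rows over the same alphabet.  Coordinates throughout the
package are 0-based, half-open.  The gap character is fixed to ``'-'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

GAP = "-"

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")

#: Residues tolerated beyond the strict alphabets (ambiguity codes).
_EXTRA = {"protein": frozenset("X*"), "dna": frozenset("N")}


class SequenceError(ValueError):
    """Malformed sequence, alignment, or FASTA input."""


@dataclass(frozen=True)
class BioSequence:
    """A named ungapped residue string.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within any collection.
    residues : str
        Upper-case residues; ``X`` (protein) / ``N`` (DNA) ambiguity allowed,
        gaps are not.
    alphabet : {"protein", "dna"}
    description : str
        Free text carried from/to FASTA headers.
    """

    id: str
    residues: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("protein", "dna"):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        allowed = (PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET) | _EXTRA[
            self.alphabet
        ]
        bad = set(self.residues) - allowed
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains symbols {sorted(bad)} not in the "
                f"{self.alphabet} alphabet (gaps are not allowed in BioSequence)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered multiple alignment: equal-length gapped rows, unique ids."""

    rows: tuple[tuple[str, str], ...]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise SequenceError("duplicate row ids in alignment")
        lengths = {len(row) for _, row in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        for rid, row in self.rows:
            ungapped = row.replace(GAP, "")
            if not ungapped:
                raise SequenceError(f"row {rid!r} is all gaps")
            BioSequence(rid, ungapped, self.alphabet)  # validates the alphabet

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], alphabet: str = "protein"
    ) -> "MultipleAlignment":
        return cls(tuple((rid, row.upper()) for rid, row in pairs), alphabet)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def column(self, j: int) -> list[str]:
        return [row[j] for _, row in self.rows]

    def ungapped(self, rid: str) -> BioSequence:
        return BioSequence(rid, self.row(rid).replace(GAP, ""), self.alphabet)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[BioSequence]:
    """Read a FASTA file into :class:`BioSequence` records (order preserved)."""
    records: list[BioSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise SequenceError(f"empty FASTA record {rec.id!r} in {path}")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(BioSequence(rec.id, seq, alphabet, desc))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Sequence[BioSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, alphabet: str = "protein") -> MultipleAlignment:
    """Read a gapped FASTA alignment."""
    rows = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate alignment id {rec.id!r}")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq).upper()))
    return MultipleAlignment.from_pairs(rows, alphabet)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.rows:
            fh.write(f">{rid}\n{row}\n")


_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code; N-containing → X."""
    if "N" in codon:
        return "X"
    try:
        return _CODON_TABLE[codon]
    except KeyError:
        raise SequenceError(f"untranslatable codon {codon!r}") from None


def translate(dna: BioSequence, frame: int = 0) -> BioSequence:
    """Translate a DNA sequence in the given reading frame.

    The trailing partial codon is dropped; stop codons become ``*``; codons
    containing ``N`` translate to ``X``.  Only ``ACGTN`` symbols are accepted.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if dna.alphabet != "dna":
        raise SequenceError(f"translate() needs a DNA sequence, got {dna.alphabet}")
    seq = dna.residues[frame:]
    if len(seq) < 3:
        raise SequenceError(f"sequence {dna.id!r}: fewer than one codon in frame {frame}")
    aa = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)]
    return BioSequence(dna.id, "".join(aa), "protein", dna.description)
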