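"""Protein sequences and FASTA I/O.

Positions are 1-based everywhere in the public interface (matrix indices,
which are 0-based, never leak out of the numerical modules).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


class SequenceError(ValueError):
    """Raised for invalid residue strings or out-of-range positions."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein sequence over the 20 canonical amino acids.

    Parameters
    ----------
    id : str
        Free-text label.
    residues : str
        Ordered one-letter residue string; must be non-empty and contain
        only canonical codes.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = sorted({c for c in self.residues if c not in AA_INDEX})
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-canonical residue(s) {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise SequenceError(
                f"position {position} out of range 1..{len(self.residues)} "
                f"for sequence {self.id!r}"
            )
        return self.residues[position - 1]

    def indices(self) -> list[int]:
        """Integer encoding (0..19 per residue, alphabetical alphabet)."""
        return [AA_INDEX[c] for c in self.residues]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read all records of a FASTA file as :class:`ProteinSequence`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    recs: Iterator[SeqRecord] = (
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    )
    SeqIO.write(recs, str(path), "fasta")
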