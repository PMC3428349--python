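"""Translation under the vertebrate mitochondrial genetic code.

Barcode records are translated codon-by-codon starting at the alignment's
frame offset.  Any codon containing a non-canonical base (missing data,
ambiguity code, or gap) translates to ``X``; stop codons translate to ``*``.
``X`` residues are excluded from amino-acid frequency denominators, mirroring
the nucleotide missing-data rule.

Code tables are taken from the NCBI numbering (default 2, vertebrate
mitochondrial: stops TAA/TAG/AGA/AGG, ATA→M, TGA→W).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

from Bio.Data import CodonTable

from .alignment_io import AlignmentSet, BarcodeRecord, CANONICAL_BASES, VlfqcError

STOP = "*"
UNKNOWN = "X"

#: Canonical amino-acid alphabet used by frequency matrices: the 20 residues
#: plus '*' (a stop observed in a record is a countable, highly diagnostic
#: residue state).  'X' is the missing marker.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + STOP


class FrameError(VlfqcError, ValueError):
    """Sequence length incompatible with the declared reading frame."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table; stops map to ``*``."""

    name: str
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code needs 64 codons, got {len(self.table)}")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 2) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            table[codon] = STOP
        return cls(name=ncbi.names[0], table=table)

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)


VERTEBRATE_MITO = GeneticCode.from_ncbi_id(2)


@dataclass
class ProteinRecord:
    """Translated record: 20 amino acids plus ``X`` (untranslatable) and ``*``."""

    record_id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def translate_sequence(
    sequence: str, frame_offset: int = 0, code: GeneticCode = VERTEBRATE_MITO
) -> str:
    if (len(sequence) - frame_offset) % 3 != 0:
        raise FrameError(
            f"length {len(sequence)} minus frame offset {frame_offset} "
            "is not divisible by 3"
        )
    out = []
    for i in range(frame_offset, len(sequence), 3):
        codon = sequence[i : i + 3]
        if any(b not in CANONICAL_BASES for b in codon):
            out.append(UNKNOWN)
        else:
            out.append(code.table[codon])
    return "".join(out)


def translate(
    record: Union[BarcodeRecord, str],
    frame_offset: int = 0,
    code: GeneticCode = VERTEBRATE_MITO,
) -> ProteinRecord:
    """Translate a record (or bare sequence) to a :class:`ProteinRecord`."""
    if isinstance(record, BarcodeRecord):
        return ProteinRecord(
            record_id=record.record_id,
            residues=translate_sequence(record.sequence, frame_offset, code),
        )
    return ProteinRecord(record_id="", residues=translate_sequence(record, frame_offset, code))


def translate_alignment(
    aln: AlignmentSet, code: GeneticCode = VERTEBRATE_MITO
) -> list[ProteinRecord]:
    """Translate every record at the alignment's frame offset.

    Trailing bases that do not fill a codon are dropped (the canonical
    648-nt trim has none).
    """
    usable = (aln.length - aln.frame_offset) // 3 * 3
    return [
        ProteinRecord(
            record_id=rec.record_id,
            residues=translate_sequence(
                rec.sequence[aln.frame_offset : aln.frame_offset + usable], 0, code
            ),
        )
        for rec in aln
    ]


def find_stops(prot: ProteinRecord) -> list[int]:
    """1-based codon positions of stop residues; empty for an open reading frame."""
    return [i + 1 for i, aa in enumerate(prot.residues) if aa == STOP]
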