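"""Reading, validating, trimming and labelling aligned barcode records.

The package works on multiple sequence alignments of protein-coding DNA
barcodes (canonically the 648-nt / 216-codon 5' region of COI).  This module
defines the in-memory alignment containers, the missing-data conventions every
downstream statistic relies on, and FASTA input/output.

Residue conventions
-------------------
* ``A C G T`` are *canonical* and enter every count.
* ``N`` and all IUPAC ambiguity codes (``R Y S W K M B D H V``) are *missing*
  data: they are excluded from column denominators.  Ambiguity codes are never
  counted fractionally — a fractional count would make the very-low-frequency
  threshold ill-defined.
* ``-`` is a *gap*.  Terminal gaps (leading/trailing runs, i.e. an incomplete
  read) are treated as missing for frequency purposes; internal gaps are
  preserved and surfaced to the pseudogene analysis, where a genuine deletion
  is diagnostic.

Coordinates are 1-based inclusive in every report and public return value,
0-based half-open internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

CANONICAL_BASES = "ACGT"
AMBIGUITY_CODES = "RYSWKMBDHVN"
GAP_CHAR = "-"
NT_ALPHABET = frozenset(CANONICAL_BASES + AMBIGUITY_CODES + GAP_CHAR)

#: Character used internally to mark positions masked as missing.
MISSING_CHAR = "N"


class VlfqcError(Exception):
    """Base class for package errors."""


class InputError(VlfqcError, ValueError):
    """Malformed or empty input."""


class AlignmentError(VlfqcError, ValueError):
    """Records violate alignment invariants (e.g. unequal lengths)."""


class HeaderParseError(VlfqcError, ValueError):
    """A FASTA header did not yield a species/cohort label."""


def residue_class(ch: str) -> str:
    """Classify a single alignment character.

    Returns ``"canonical"`` for A/C/G/T, ``"missing"`` for N and IUPAC
    ambiguity codes, ``"gap"`` for ``-``.  Raises :class:`InputError` for
    anything else.
    """
    if len(ch) != 1:
        raise InputError(f"residue_class expects a single character, got {ch!r}")
    c = ch.upper()
    if c in CANONICAL_BASES:
        return "canonical"
    if c in AMBIGUITY_CODES:
        return "missing"
    if c == GAP_CHAR:
        return "gap"
    raise InputError(f"character {ch!r} is outside the nucleotide alphabet")


HeaderRule = Callable[[str], Optional[str]]


def pipe_field(index: int, *, required: bool = True) -> HeaderRule:
    """Header rule extracting the 1-based ``|``-delimited field of a header.

    With ``required=False`` the rule returns ``None`` when the field is absent
    or empty (useful for optional cohort labels).
    """

    def rule(header: str) -> Optional[str]:
        parts = header.split("|")
        if index <= len(parts):
            value = parts[index - 1].strip()
            if value:
                return value
        if required:
            raise HeaderParseError(
                f"header {header!r} has no field {index} under '|'-splitting"
            )
        return None

    return rule


def regex_rule(pattern: str, *, required: bool = True) -> HeaderRule:
    """Header rule extracting group 1 of ``pattern`` from the full header."""
    compiled = re.compile(pattern)

    def rule(header: str) -> Optional[str]:
        m = compiled.search(header)
        if m is not None and m.group(1):
            return m.group(1).strip()
        if required:
            raise HeaderParseError(f"header {header!r} does not match {pattern!r}")
        return None

    return rule


def _as_rule(pattern, *, required: bool) -> HeaderRule:
    if pattern is None:
        raise ValueError("pattern is None")
    if callable(pattern):
        return pattern
    return regex_rule(str(pattern), required=required)


#: Default species rule: second '|'-delimited header field (e.g. ">X1|Homo sapiens").
DEFAULT_SPECIES_RULE: HeaderRule = pipe_field(2)
#: Default cohort rule: optional third '|'-delimited field.
DEFAULT_COHORT_RULE: HeaderRule = pipe_field(3, required=False)


@dataclass
class BarcodeRecord:
    """One aligned barcode sequence with its species (and optional cohort) label."""

    record_id: str
    species: str
    sequence: str
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise InputError("record_id must be non-empty")
        if not self.species:
            raise HeaderParseError(f"record {self.record_id!r}: empty species label")
        self.sequence = self.sequence.upper()
        for i, ch in enumerate(self.sequence):
            if ch not in NT_ALPHABET:
                raise InputError(
                    f"record {self.record_id!r}: invalid character {ch!r} "
                    f"at position {i + 1}"
                )

    def core_span(self) -> tuple[int, int]:
        """0-based half-open span between the first and last non-gap residue.

        Positions outside the span are terminal gaps and are treated as
        missing data by every frequency computation.  An all-gap sequence
        yields the empty span ``(0, 0)``.
        """
        stripped = self.sequence.strip(GAP_CHAR)
        if not stripped:
            return (0, 0)
        start = len(self.sequence) - len(self.sequence.lstrip(GAP_CHAR))
        return (start, start + len(stripped))

    def internal_gap_runs(self) -> list[tuple[int, int]]:
        """Internal gap runs as ``(start_1based, length)`` pairs."""
        start, end = self.core_span()
        runs: list[tuple[int, int]] = []
        i = start
        while i < end:
            if self.sequence[i] == GAP_CHAR:
                j = i
                while j < end and self.sequence[j] == GAP_CHAR:
                    j += 1
                runs.append((i + 1, j - i))
                i = j
            else:
                i += 1
        return runs

    def effective_residue(self, pos0: int) -> str:
        """Residue at 0-based position with terminal gaps mapped to missing."""
        start, end = self.core_span()
        if pos0 < start or pos0 >= end:
            return MISSING_CHAR
        return self.sequence[pos0]


@dataclass
class AlignmentSet:
    """An ordered collection of equal-length barcode records.

    ``frame_offset`` is the 0-based offset of the first complete codon's first
    base within the (trimmed) region; canonically 0 for the standard barcode
    trim, where position 1 opens a codon.
    """

    records: list[BarcodeRecord]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("an AlignmentSet needs at least one record")
        length = len(self.records[0].sequence)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"record {rec.record_id!r} has length {len(rec.sequence)}, "
                    f"expected {length}"
                )
            if rec.record_id in seen:
                raise AlignmentError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
        if not (0 <= self.frame_offset < 3):
            raise InputError("frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlignmentSet):
            return NotImplemented
        return (
            self.frame_offset == other.frame_offset
            and self.records == other.records
        )

    def get(self, record_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def species_counts(self) -> dict[str, int]:
        """Species label -> number of records carrying it."""
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.species] = counts.get(rec.species, 0) + 1
        return counts

    def records_by_species(self) -> dict[str, list[BarcodeRecord]]:
        by: dict[str, list[BarcodeRecord]] = {}
        for rec in self.records:
            by.setdefault(rec.species, []).append(rec)
        return by

    def effective_matrix(self) -> np.ndarray:
        """(n_records, length) byte matrix with terminal gaps masked as missing.

        Ambiguity codes are left as-is (anything outside ACGT and ``-`` counts
        as missing downstream); terminal-gap positions are rewritten to ``N``.
        """
        joined = "".join(rec.sequence for rec in self.records)
        mat = (
            np.frombuffer(joined.encode("ascii"), dtype="S1")
            .reshape(len(self.records), self.length)
            .copy()
        )
        for i, rec in enumerate(self.records):
            start, end = rec.core_span()
            if start > 0:
                mat[i, :start] = MISSING_CHAR.encode()
            if end < self.length:
                mat[i, end:] = MISSING_CHAR.encode()
        return mat


def read_alignment(
    path: Union[str, Path],
    species_pattern=None,
    cohort_pattern=None,
) -> AlignmentSet:
    """Read a multi-FASTA alignment, parsing species (and cohort) from headers.

    ``species_pattern``/``cohort_pattern`` may be a callable taking the full
    header line (description) or a regex string whose group 1 is the label.
    The defaults take the second and third ``|``-delimited fields; the cohort
    is optional.
    """
    species_rule = (
        DEFAULT_SPECIES_RULE
        if species_pattern is None
        else _as_rule(species_pattern, required=True)
    )
    cohort_rule = (
        DEFAULT_COHORT_RULE
        if cohort_pattern is None
        else _as_rule(cohort_pattern, required=False)
    )
    records: list[BarcodeRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        header = seqrec.description
        species = species_rule(header)
        if not species:
            raise HeaderParseError(f"header {header!r}: no species label")
        cohort = cohort_rule(header)
        records.append(
            BarcodeRecord(
                record_id=seqrec.id.split("|")[0],
                species=species,
                sequence=str(seqrec.seq),
                cohort=cohort,
            )
        )
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return AlignmentSet(records=records)


def write_alignment(aln: AlignmentSet, path: Union[str, Path], *, wrap: int = 70) -> None:
    """Write the alignment as multi-FASTA, ``id|species[|cohort]`` headers.

    Sequences are wrapped at ``wrap`` columns.  The dialect round-trips
    through :func:`read_alignment` with the default header rules.
    """
    with open(path, "w") as fh:
        for rec in aln:
            header = f"{rec.record_id}|{rec.species}"
            if rec.cohort is not None:
                header += f"|{rec.cohort}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def trim_to_barcode(
    aln: AlignmentSet, start: int, length: int, *, frame_offset: int = 0
) -> AlignmentSet:
    """Slice the alignment to columns ``[start, start+length-1]`` (1-based).

    ``frame_offset`` is the caller's declaration of where the first complete
    codon opens within the trimmed region (the standard barcode trim opens a
    codon at position 1, offset 0).
    """
    if start < 1 or length < 1 or start + length - 1 > aln.length:
        raise AlignmentError(
            f"trim window [{start}, {start + length - 1}] exceeds alignment "
            f"of length {aln.length}"
        )
    lo = start - 1
    records = [
        replace(rec, sequence=rec.sequence[lo : lo + length]) for rec in aln
    ]
    return AlignmentSet(records=records, frame_offset=frame_offset)


def concatenate(alns: Sequence[AlignmentSet]) -> AlignmentSet:
    """Concatenate record sets of equal-length alignments (e.g. cohorts)."""
    if not alns:
        raise InputError("nothing to concatenate")
    frame = alns[0].frame_offset
    length = alns[0].length
    records: list[BarcodeRecord] = []
    for a in alns:
        if a.length != length or a.frame_offset != frame:
            raise AlignmentError("alignments differ in length or frame")
        records.extend(a.records)
    return AlignmentSet(records=records, frame_offset=frame)
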