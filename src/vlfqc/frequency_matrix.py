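"""Per-position residue frequency matrices, modal sequences, and conservation.

The frequency matrix is the core data structure of the whole QC approach: for
every alignment column the fraction of sequences carrying each residue is
recorded, *excluding missing data from the denominator*.  The most abundant
(1st modal) and second most abundant (2nd modal) residues define the modal
sequences against which every record is compared, and near-but-not-complete
conservation is what makes very-low-frequency variants detectable at all.

Ties between equal counts are broken alphabetically and flagged, so modal
sequences are deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

from ._util import exact_fraction, round_half_up
from .alignment_io import AlignmentSet, CANONICAL_BASES, GAP_CHAR, InputError
from .codon_translate import AA_ALPHABET, ProteinRecord, UNKNOWN

NT = "nt"
AA = "aa"

_ALPHABETS = {NT: CANONICAL_BASES, AA: AA_ALPHABET}

#: Placeholder emitted in modal sequences where no residue is available.
MODAL_PLACEHOLDER = "."


def codon_class(position: int, frame_offset: int = 0) -> int:
    """Codon position class (1, 2 or 3) of a 1-based nucleotide position."""
    return (position - 1 - frame_offset) % 3 + 1


@dataclass
class ResidueColumn:
    """Residue counts and modal summary for one alignment column.

    ``n_scored`` counts records with a canonical residue here; missing data
    (N, ambiguity codes, terminal gaps) and internal gaps are excluded from
    the denominator.  Fractions are exact count ratios; ``frac`` exposes them
    as :class:`fractions.Fraction` for threshold comparisons.
    """

    position: int
    counts: dict[str, int]
    n_scored: int
    n_gap: int = 0
    n_missing: int = 0
    modal1: Optional[str] = None
    modal1_frac: float = 0.0
    modal2: Optional[str] = None
    modal2_frac: float = 0.0
    tie: bool = False

    @property
    def scorable(self) -> bool:
        return self.n_scored > 0

    def frac(self, residue: str) -> Fraction:
        if self.n_scored == 0:
            return Fraction(0)
        return Fraction(self.counts.get(residue, 0), self.n_scored)


@dataclass
class FrequencyMatrix:
    """Ordered per-position residue columns for one alphabet (``nt``/``aa``)."""

    alphabet: str
    columns: list[ResidueColumn]
    frame_offset: int = 0

    @property
    def length(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)

    def column(self, position: int) -> ResidueColumn:
        """Column at 1-based position."""
        return self.columns[position - 1]


def _rank_column(position: int, counts: dict[str, int], n_gap: int, n_missing: int) -> ResidueColumn:
    n_scored = sum(counts.values())
    col = ResidueColumn(
        position=position,
        counts=counts,
        n_scored=n_scored,
        n_gap=n_gap,
        n_missing=n_missing,
    )
    if n_scored == 0:
        return col
    # sort by count desc, then alphabetically: the stated deterministic tie-break
    ranked = sorted(
        ((res, c) for res, c in counts.items() if c > 0),
        key=lambda rc: (-rc[1], rc[0]),
    )
    col.modal1, c1 = ranked[0]
    col.modal1_frac = c1 / n_scored
    if len(ranked) > 1:
        col.modal2, c2 = ranked[1]
        col.modal2_frac = c2 / n_scored
        col.tie = c1 == c2
    return col


def build_matrix(
    source: Union[AlignmentSet, Sequence[ProteinRecord]],
    alphabet: Optional[str] = None,
) -> FrequencyMatrix:
    """Build the frequency matrix of an alignment (nt) or protein set (aa).

    Every column's fractions are counts over ``n_scored``; columns where no
    record is scorable are kept in place but marked unscorable and excluded
    from summaries.
    """
    if isinstance(source, AlignmentSet):
        if alphabet not in (None, NT):
            raise InputError("an AlignmentSet builds a nucleotide matrix")
        mat = source.effective_matrix()
        residues = CANONICAL_BASES
        frame_offset = source.frame_offset
        track_gaps = True
    else:
        proteins = list(source)
        if not proteins:
            raise InputError("empty protein set")
        if alphabet not in (None, AA):
            raise InputError("a protein set builds an amino-acid matrix")
        length = len(proteins[0].residues)
        for p in proteins:
            if len(p.residues) != length:
                raise InputError("protein records differ in length")
        joined = "".join(p.residues for p in proteins)
        mat = np.frombuffer(joined.encode("ascii"), dtype="S1").reshape(
            len(proteins), length
        )
        residues = AA_ALPHABET
        frame_offset = 0
        track_gaps = False

    n_records, length = mat.shape
    residue_bytes = [(r, r.encode()) for r in residues]
    columns: list[ResidueColumn] = []
    gap_b = GAP_CHAR.encode()
    for j in range(length):
        col = mat[:, j]
        counts = {r: int((col == rb).sum()) for r, rb in residue_bytes}
        n_gap = int((col == gap_b).sum()) if track_gaps else 0
        n_missing = n_records - sum(counts.values()) - n_gap
        columns.append(_rank_column(j + 1, counts, n_gap, n_missing))
    return FrequencyMatrix(
        alphabet=NT if isinstance(source, AlignmentSet) else AA,
        columns=columns,
        frame_offset=frame_offset,
    )


def modal_sequence(fm: FrequencyMatrix, rank: int = 1) -> str:
    """Concatenate modal residues (rank 1 or 2) across all columns.

    Columns without the requested residue (unscorable columns; rank-2 at
    invariant columns) contribute the ``.`` placeholder.
    """
    if rank not in (1, 2):
        raise InputError("rank must be 1 or 2")
    out = []
    for col in fm:
        res = col.modal1 if rank == 1 else col.modal2
        out.append(res if res is not None else MODAL_PLACEHOLDER)
    return "".join(out)


def count_differences(
    sequence: str,
    modal: str,
    frame_offset: int = 0,
    alphabet: str = NT,
) -> dict:
    """Count positions where a record differs from the modal sequence.

    Positions where the record carries missing data or a gap (nt) or an
    untranslatable ``X`` (aa) are not counted as differences.  Nucleotide
    counts are partitioned by codon class (keys 1, 2, 3); amino-acid counts
    come back under the single key ``"aa"``.
    """
    if len(sequence) != len(modal):
        raise InputError(
            f"sequence length {len(sequence)} != modal length {len(modal)}"
        )
    canonical = _ALPHABETS[NT] if alphabet == NT else set(AA_ALPHABET)
    if alphabet == NT:
        diffs = {1: 0, 2: 0, 3: 0}
    else:
        diffs = {"aa": 0}
    # terminal gaps in the raw sequence are not canonical, so they skip naturally
    seq = sequence
    if alphabet == NT:
        # mask terminal gaps as missing so they never count as differences
        stripped = seq.strip(GAP_CHAR)
        lo = len(seq) - len(seq.lstrip(GAP_CHAR)) if stripped else len(seq)
        hi = lo + len(stripped)
    else:
        lo, hi = 0, len(seq)
    for i, (a, b) in enumerate(zip(seq, modal)):
        if i < lo or i >= hi:
            continue
        if a not in canonical or (alphabet == AA and a == UNKNOWN):
            continue
        if b == MODAL_PLACEHOLDER:
            continue
        if a != b:
            if alphabet == NT:
                diffs[codon_class(i + 1, frame_offset)] += 1
            else:
                diffs["aa"] += 1
    return diffs


@dataclass
class ClassConservation:
    """Conservation summary for one position class (codon 1/2/3 or amino acid)."""

    label: str
    n_sites: int
    n_fully_conserved: int
    n_modal1_above: int
    n_modal12_above: int
    mean_diffs: float
    diffs_min: int
    diffs_max: int

    def percentages(self) -> tuple[int, int, int]:
        """Integer percentages (half-up) of the three conservation buckets."""
        if self.n_sites == 0:
            return (0, 0, 0)
        return tuple(
            int(round_half_up(100 * n / self.n_sites))
            for n in (
                self.n_fully_conserved,
                self.n_modal1_above,
                self.n_modal12_above,
            )
        )


#: A conservation summary: class label -> ClassConservation.
ConservationSummary = dict


def conservation_summary(
    fm: FrequencyMatrix,
    per_record_diffs: Sequence[dict],
    threshold=Fraction(999, 1000),
) -> ConservationSummary:
    """Bucket columns by conservation and summarise differences vs 1st modal.

    ``threshold`` is a strict lower bound on the *exact* count ratio (default
    999/1000, the complement of the 0.1% VLF cut): a column counts as
    "modal1 above" iff modal1's fraction exceeds it exactly, never after
    rounding.  Unscorable columns are excluded from class sizes.
    """
    thr = exact_fraction(threshold)
    if fm.alphabet == NT:
        labels = {1: "codon1", 2: "codon2", 3: "codon3"}
        classes = {
            col.position: codon_class(col.position, fm.frame_offset) for col in fm
        }
        diff_keys = {1: 1, 2: 2, 3: 3}
    else:
        labels = {"aa": "amino_acid"}
        classes = {col.position: "aa" for col in fm}
        diff_keys = {"aa": "aa"}

    summary: ConservationSummary = {}
    for key, label in labels.items():
        cols = [c for c in fm if classes[c.position] == key and c.scorable]
        n_full = sum(1 for c in cols if c.counts[c.modal1] == c.n_scored)
        n_m1 = sum(1 for c in cols if c.frac(c.modal1) > thr)
        n_m12 = sum(
            1
            for c in cols
            if c.frac(c.modal1) + (c.frac(c.modal2) if c.modal2 else 0) > thr
        )
        diffs = [d[diff_keys[key]] for d in per_record_diffs]
        summary[label] = ClassConservation(
            label=label,
            n_sites=len(cols),
            n_fully_conserved=n_full,
            n_modal1_above=n_m1,
            n_modal12_above=n_m12,
            mean_diffs=float(np.mean(diffs)) if diffs else 0.0,
            diffs_min=min(diffs) if diffs else 0,
            diffs_max=max(diffs) if diffs else 0,
        )
    return summary


def codon_class_variance_ratio(summary: ConservationSummary) -> tuple[float, float, float]:
    """Ratio of per-class mean differences vs 1st modal, normalised to codon 2.

    Second codon positions are the most constrained class, so the ratio reads
    as "times the codon-2 variability".  Undefined when the codon-2 mean is 0.
    """
    try:
        m1 = summary["codon1"].mean_diffs
        m2 = summary["codon2"].mean_diffs
        m3 = summary["codon3"].mean_diffs
    except KeyError as exc:
        raise InputError("summary lacks a codon class") from exc
    if m2 == 0:
        raise InputError("codon-2 mean differences is zero; ratio undefined")
    return (m1 / m2, 1.0, m3 / m2)
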