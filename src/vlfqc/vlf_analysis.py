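"""Very-low-frequency variant detection, classification, and spatial profiles.

A very-low-frequency variant (VLF) is a residue carried by fewer than 0.1%
of the sequences scored at its column (strict ``<`` on the exact count
ratio; the denominator is the column's non-missing count).  VLFs are sorted
within species:

* ``singleton`` — exactly one individual of a species carries the residue at
  that position, and the species has at least two records.  The spatial
  signature of singletons (concentration at the segment ends, where Sanger
  read quality decays) marks them as probable sequencing errors.
* ``shared`` — two or more conspecific individuals carry the *same* residue
  at the *same* position, suggesting an inherited biological variant (or a
  co-amplified pseudogene when many cluster in one record).
* ``indeterminate`` — the species has a single record, so sharing cannot be
  assessed; these are excluded from singleton/shared tabulations and from
  the error-rate numerator.

Note the scale-dependence of the cut: at the default 0.1%, a variant carried
by two records can only qualify in datasets of more than 2,000 sequences.
Smaller studies should widen ``threshold`` proportionally (see docs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from ._util import exact_fraction, round_half_up
from .alignment_io import AlignmentSet, CANONICAL_BASES, InputError
from .codon_translate import (
    AA_ALPHABET,
    GeneticCode,
    ProteinRecord,
    VERTEBRATE_MITO,
    translate_alignment,
)
from .frequency_matrix import AA, NT, FrequencyMatrix, codon_class

SINGLETON = "singleton"
SHARED = "shared"
INDETERMINATE = "indeterminate"
STATUSES = (SINGLETON, SHARED, INDETERMINATE)


@dataclass(frozen=True)
class VariantObservation:
    """One (record, position, residue) occurrence of a very-low-frequency residue."""

    record_id: str
    species: str
    position: int  # 1-based; nt column or codon index depending on alphabet
    residue: str
    column_frac: float
    alphabet: str  # "nt" | "aa"
    codon_class: Optional[int] = None  # 1/2/3 for nt, None for aa
    status: Optional[str] = None


def detect_vlfs(
    fm: FrequencyMatrix,
    aln: AlignmentSet,
    threshold=0.001,
    proteins: Optional[Sequence[ProteinRecord]] = None,
    code: GeneticCode = VERTEBRATE_MITO,
) -> list[VariantObservation]:
    """Emit one observation per (record, position) carrying a sub-threshold residue.

    The 1st modal residue is never emitted, even if degenerately rare.  For an
    amino-acid matrix, translated records are taken from ``proteins`` or
    computed from ``aln`` under ``code``.
    """
    thr = exact_fraction(threshold)
    if not (0 < thr < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    species_of = {rec.record_id: rec.species for rec in aln}

    if fm.alphabet == NT:
        mat = aln.effective_matrix()
        ids = [rec.record_id for rec in aln]
        residues = CANONICAL_BASES
    else:
        prots = list(proteins) if proteins is not None else translate_alignment(aln, code)
        if len(prots) != len(aln):
            raise InputError("protein set does not match alignment")
        joined = "".join(p.residues for p in prots)
        mat = np.frombuffer(joined.encode("ascii"), dtype="S1").reshape(
            len(prots), len(prots[0].residues)
        )
        ids = [p.record_id for p in prots]
        residues = AA_ALPHABET

    observations: list[VariantObservation] = []
    for col in fm:
        if not col.scorable:
            continue
        rare = [
            res
            for res in residues
            if 0 < col.counts.get(res, 0)
            and res != col.modal1
            and col.frac(res) < thr
        ]
        if not rare:
            continue
        column = mat[:, col.position - 1]
        for res in rare:
            frac = float(col.frac(res))
            for i in np.flatnonzero(column == res.encode()):
                observations.append(
                    VariantObservation(
                        record_id=ids[i],
                        species=species_of[ids[i]],
                        position=col.position,
                        residue=res,
                        column_frac=frac,
                        alphabet=fm.alphabet,
                        codon_class=(
                            codon_class(col.position, fm.frame_offset)
                            if fm.alphabet == NT
                            else None
                        ),
                    )
                )
    observations.sort(key=lambda o: (o.position, o.record_id, o.residue))
    return observations


def classify_by_species(
    observations: Sequence[VariantObservation], aln: AlignmentSet
) -> list[VariantObservation]:
    """Assign singleton/shared/indeterminate status within species.

    Shared status is residue-specific: two conspecific records with
    *different* rare residues at one position yield two singletons.
    """
    n_records = aln.species_counts()
    carriers: dict[tuple, set] = {}
    for obs in observations:
        key = (obs.alphabet, obs.species, obs.position, obs.residue)
        carriers.setdefault(key, set()).add(obs.record_id)

    out = []
    for obs in observations:
        key = (obs.alphabet, obs.species, obs.position, obs.residue)
        if n_records.get(obs.species, 0) <= 1:
            status = INDETERMINATE
        elif len(carriers[key]) >= 2:
            status = SHARED
        else:
            status = SINGLETON
        out.append(replace(obs, status=status))
    return out


def mean_per_sequence(n_vlfs: int, n_sequences: int) -> float:
    """Mean VLFs per sequence bearing one, rounded half-up to one decimal."""
    if n_sequences == 0:
        return 0.0
    return round_half_up(n_vlfs / n_sequences, 1)


@dataclass
class ConcordanceRow:
    """One status row of the VLF census: per-alphabet totals plus nt/aa overlap."""

    status: str
    nt_vlfs: int
    nt_seqs: int
    nt_mean: float
    nt_range: tuple[int, int]
    aa_vlfs: int
    aa_seqs: int
    aa_mean: float
    aa_range: tuple[int, int]
    nt_only: int
    aa_only: int
    both: int


#: status label -> ConcordanceRow ("singleton", "shared", optionally "pseudogene").
ConcordanceTable = dict


def _row(
    status_label: str,
    nt_obs: Sequence[VariantObservation],
    aa_obs: Sequence[VariantObservation],
) -> ConcordanceRow:
    def tally(obs):
        per_seq: dict[str, int] = {}
        for o in obs:
            per_seq[o.record_id] = per_seq.get(o.record_id, 0) + 1
        counts = list(per_seq.values())
        return (
            len(obs),
            len(per_seq),
            mean_per_sequence(len(obs), len(per_seq)),
            (min(counts), max(counts)) if counts else (0, 0),
            set(per_seq),
        )

    nt_n, nt_s, nt_m, nt_r, nt_ids = tally(nt_obs)
    aa_n, aa_s, aa_m, aa_r, aa_ids = tally(aa_obs)
    return ConcordanceRow(
        status=status_label,
        nt_vlfs=nt_n,
        nt_seqs=nt_s,
        nt_mean=nt_m,
        nt_range=nt_r,
        aa_vlfs=aa_n,
        aa_seqs=aa_s,
        aa_mean=aa_m,
        aa_range=aa_r,
        nt_only=len(nt_ids - aa_ids),
        aa_only=len(aa_ids - nt_ids),
        both=len(nt_ids & aa_ids),
    )


def concordance(
    nt_obs: Sequence[VariantObservation],
    aa_obs: Sequence[VariantObservation],
    pseudogene_ids: Optional[set] = None,
) -> ConcordanceTable:
    """Cross-tabulate classified nt and aa VLFs by status, per sequence.

    Indeterminate observations are excluded (single-record species).  When
    ``pseudogene_ids`` is given, an extra row restricts shared VLFs to the
    flagged records — the "pseudogene subset" of the census.
    """
    table: ConcordanceTable = {}
    for status in (SINGLETON, SHARED):
        table[status] = _row(
            status,
            [o for o in nt_obs if o.status == status],
            [o for o in aa_obs if o.status == status],
        )
    if pseudogene_ids is not None:
        table["pseudogene"] = _row(
            "pseudogene",
            [o for o in nt_obs if o.status == SHARED and o.record_id in pseudogene_ids],
            [o for o in aa_obs if o.status == SHARED and o.record_id in pseudogene_ids],
        )
    return table


@dataclass
class SpatialProfile:
    """Spatial distribution of observations (histogram or sliding window)."""

    kind: str  # "histogram" | "sliding_window"
    bin_or_window: int
    length: int
    starts: list[int]  # 1-based start of each bin/window
    counts: dict[str, np.ndarray]  # status -> per-bin counts
    positions: dict[str, list[int]]  # status -> raw observation positions

    def total(self, status: Optional[str] = None) -> int:
        if status is None:
            return sum(len(v) for v in self.positions.values())
        return len(self.positions.get(status, []))


def _positions_by_status(observations) -> dict[str, list[int]]:
    by: dict[str, list[int]] = {}
    for o in observations:
        by.setdefault(o.status or "unclassified", []).append(o.position)
    return by


def positional_histogram(
    observations: Sequence[VariantObservation],
    bin_width: int = 50,
    length: int = 648,
) -> SpatialProfile:
    """Counts per ``bin_width``-nt bin per status; bins tile [1, length].

    When ``bin_width`` does not divide ``length`` the last bin is truncated.
    """
    if bin_width < 1:
        raise InputError("bin_width must be positive")
    starts = list(range(1, length + 1, bin_width))
    positions = _positions_by_status(observations)
    edges = starts + [length + 1]
    counts = {
        status: np.histogram(pos, bins=edges)[0]
        for status, pos in positions.items()
    }
    return SpatialProfile(
        kind="histogram",
        bin_or_window=bin_width,
        length=length,
        starts=starts,
        counts=counts,
        positions=positions,
    )


def sliding_window_profile(
    observations: Sequence[VariantObservation],
    window: int = 30,
    step: int = 1,
    length: int = 648,
) -> SpatialProfile:
    """For each window start s, count observations in [s, s+window-1]."""
    if window < 1 or window > length:
        raise InputError("window must lie in [1, length]")
    starts = list(range(1, length - window + 2, step))
    positions = _positions_by_status(observations)
    counts = {}
    for status, pos in positions.items():
        arr = np.zeros(length + 1, dtype=int)
        for p in pos:
            arr[p] += 1
        csum = np.concatenate([[0], np.cumsum(arr)])
        counts[status] = np.array(
            [csum[min(s + window, length + 1)] - csum[s] for s in starts]
        )
    return SpatialProfile(
        kind="sliding_window",
        bin_or_window=window,
        length=length,
        starts=starts,
        counts=counts,
        positions=positions,
    )


def terminal_enrichment(
    profile: SpatialProfile,
    terminal_span: int = 100,
    status: Optional[str] = None,
) -> float:
    """Observed / expected fraction of observations in the two terminal spans.

    The expectation is the uniform share ``2 * terminal_span / length``; a
    ratio of 1 means no terminal concentration.  NaN when the (status-
    filtered) observation set is empty.  Descriptive only — no test attached.
    """
    if terminal_span < 1 or 2 * terminal_span > profile.length:
        raise InputError("terminal_span must lie in [1, length/2]")
    if status is None:
        pos = [p for v in profile.positions.values() for p in v]
    else:
        pos = profile.positions.get(status, [])
    if not pos:
        return math.nan
    lo, hi = terminal_span, profile.length - terminal_span
    in_terminal = sum(1 for p in pos if p <= lo or p > hi)
    expected = 2 * terminal_span / profile.length
    return (in_terminal / len(pos)) / expected
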