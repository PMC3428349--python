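"""Sequencing-error-rate estimation, K2P distances, pseudogene flagging, cohorts.

The error-rate estimator exploits the conservation hierarchy of protein-coding
sequence: second codon positions are so constrained that essentially any
sequencing error there surfaces as a singleton very-low-frequency variant.
Assuming errors strike all codon positions equally, the per-nucleotide rate is

    rate = n_singleton_codon2 / (n_records_multi * n_codon2_sites)

where the denominator counts only records of species with two or more records
(single-record species cannot be classified and are excluded from both sides).
Because some singletons may be genuine rare variants, the estimate is an
*upper bound* on the true error rate.

Cryptic pseudogenes — nuclear mitochondrial copies (NUMTs) co-amplified by
barcode primers that pass the usual stop-codon screen — betray themselves as
records whose amino-acid VLFs are shared among conspecifics.  Flagging is
based solely on the shared-aaVLF count; stop codons, internal indels and deep
conspecific K2P divergence are reported as corroborating evidence, not gates,
precisely because the interesting cases are the ones the stop-codon screen
misses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .alignment_io import AlignmentSet, CANONICAL_BASES, InputError, VlfqcError
from .codon_translate import GeneticCode, VERTEBRATE_MITO, find_stops, translate_alignment
from .vlf_analysis import SHARED, SINGLETON, VariantObservation


class SaturationError(VlfqcError, ValueError):
    """K2P log-domain violation (too many substitutions to correct)."""

    def __init__(self, msg: str, n_sites: int, n_transitions: int, n_transversions: int):
        super().__init__(msg)
        self.n_sites = n_sites
        self.n_transitions = n_transitions
        self.n_transversions = n_transversions


@dataclass
class ErrorRateEstimate:
    """Upper-bound sequencing error rate with its numerator/denominator bookkeeping."""

    n_singleton_codon2: int
    n_records_multi: int
    n_codon2_sites: int
    barcode_length: int = 648

    def __post_init__(self) -> None:
        if self.n_records_multi <= 0 or self.n_codon2_sites <= 0:
            raise InputError("error-rate denominator must be positive")

    @property
    def rate_per_nt(self) -> float:
        return self.n_singleton_codon2 / (self.n_records_multi * self.n_codon2_sites)

    @property
    def rate_per_barcode(self) -> float:
        return self.rate_per_nt * self.barcode_length

    @classmethod
    def from_counts(
        cls,
        n_singleton_codon2: int,
        n_records_multi: int,
        n_codon2_sites: int = 216,
        barcode_length: int = 648,
    ) -> "ErrorRateEstimate":
        return cls(n_singleton_codon2, n_records_multi, n_codon2_sites, barcode_length)


def n_records_multi_from_totals(n_records: int, n_single_record_species: int) -> int:
    """Denominator from printed totals: records minus single-sequence species.

    Each species with a single sequence contributes exactly one excluded
    record, so the multi-record denominator is the difference.
    """
    if n_single_record_species > n_records:
        raise InputError("more single-record species than records")
    return n_records - n_single_record_species


def estimate_error_rate(
    observations: Sequence[VariantObservation], aln: AlignmentSet
) -> ErrorRateEstimate:
    """Estimate the upper-bound error rate from classified nucleotide VLFs.

    Numerator: singleton VLFs at second codon positions.  Denominator:
    records of species with >=2 records, times the number of second-codon
    sites.  Observations must carry ``codon_class`` and ``status``.
    """
    for obs in observations:
        if obs.alphabet != "nt" or obs.status is None:
            raise InputError(
                "estimate_error_rate needs classified nucleotide observations"
            )
    numerator = sum(
        1 for o in observations if o.status == SINGLETON and o.codon_class == 2
    )
    counts = aln.species_counts()
    n_multi = sum(1 for rec in aln if counts[rec.species] >= 2)
    if n_multi == 0:
        raise InputError("no records from species with >=2 records")
    n_codon2 = (aln.length - aln.frame_offset) // 3
    return ErrorRateEstimate(
        n_singleton_codon2=numerator,
        n_records_multi=n_multi,
        n_codon2_sites=n_codon2,
        barcode_length=aln.length,
    )


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance (substitutions/site), pairwise deletion.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the transition and
    transversion proportions over sites where both sequences carry a
    canonical base.  Raises :class:`SaturationError` when the correction's
    log arguments leave their domain.
    """
    if len(seq1) != len(seq2):
        raise InputError("sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in CANONICAL_BASES or b not in CANONICAL_BASES:
            continue
        n += 1
        if a != b:
            if frozenset((a, b)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise InputError("no pairwise-complete site")
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: P={P:.4f}, Q={Q:.4f} over {n} sites",
            n_sites=n,
            n_transitions=ts,
            n_transversions=tv,
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


#: Advisory K2P divergence above which a candidate's conspecific distance is
#: called "deep" (most closely related species differ by 2% or more).
DEEP_DIVERGENCE = 0.02


@dataclass
class PseudogeneFlag:
    """Per-record pseudogene evidence: shared aaVLF count plus corroboration."""

    record_id: str
    species: str
    n_shared_aavlfs: int
    has_stop: bool
    has_internal_indel: bool
    has_frameshift_indel: bool
    min_k2p_to_conspecific_nonvlf: Optional[float]
    verdict: str  # "candidate" | "clear"

    @property
    def deeply_divergent(self) -> Optional[bool]:
        if self.min_k2p_to_conspecific_nonvlf is None:
            return None
        return self.min_k2p_to_conspecific_nonvlf >= DEEP_DIVERGENCE


def flag_pseudogene_candidates(
    aa_observations: Sequence[VariantObservation],
    aln: AlignmentSet,
    threshold: int = 3,
    code: GeneticCode = VERTEBRATE_MITO,
) -> list[PseudogeneFlag]:
    """Flag records whose shared amino-acid VLF count reaches ``threshold``.

    Returns one flag per record bearing at least one shared aaVLF, sorted by
    record id; ``verdict`` is "candidate" at/above the threshold.  Candidates
    in species that also have non-candidate conspecifics get the minimum K2P
    distance to those conspecifics (saturated pairs are skipped).
    """
    if threshold < 1:
        raise InputError("threshold must be >= 1")
    shared_counts: dict[str, int] = {}
    for obs in aa_observations:
        if obs.alphabet != "aa":
            raise InputError("flagging needs amino-acid observations")
        if obs.status == SHARED:
            shared_counts[obs.record_id] = shared_counts.get(obs.record_id, 0) + 1
    if not shared_counts:
        return []

    proteins = {p.record_id: p for p in translate_alignment(aln, code)}
    by_species = aln.records_by_species()
    candidate_ids = {rid for rid, n in shared_counts.items() if n >= threshold}

    flags = []
    for rid in sorted(shared_counts):
        rec = aln.get(rid)
        runs = rec.internal_gap_runs()
        is_candidate = rid in candidate_ids
        min_k2p = None
        if is_candidate:
            for other in by_species[rec.species]:
                if other.record_id == rid or other.record_id in candidate_ids:
                    continue
                try:
                    d = k2p_distance(rec.sequence, other.sequence)
                except (SaturationError, InputError):
                    continue
                if min_k2p is None or d < min_k2p:
                    min_k2p = d
        flags.append(
            PseudogeneFlag(
                record_id=rid,
                species=rec.species,
                n_shared_aavlfs=shared_counts[rid],
                has_stop=bool(find_stops(proteins[rid])),
                has_internal_indel=bool(runs),
                has_frameshift_indel=any(length % 3 for _, length in runs),
                min_k2p_to_conspecific_nonvlf=min_k2p,
                verdict="candidate" if is_candidate else "clear",
            )
        )
    return flags


@dataclass
class CohortStats:
    """Per-cohort prevalence of records bearing >=1 singleton nucleotide VLF."""

    cohort: str
    n_records: int
    n_with_singleton_nvlf: int
    prevalence: float
    ci95: tuple[float, float]


#: cohort label -> CohortStats.
CohortComparison = dict


def compare_cohorts(
    aln: AlignmentSet, observations: Sequence[VariantObservation]
) -> CohortComparison:
    """Singleton-nVLF prevalence per cohort with Wilson 95% confidence intervals.

    Records without a cohort label are ignored; empty cohorts are skipped
    with a warning.  Any exclusion predicate (conspecific-free records,
    known pseudogenes, ...) is the caller's job, applied upstream.
    """
    singleton_bearers = {
        o.record_id for o in observations if o.status == SINGLETON and o.alphabet == "nt"
    }
    cohorts: dict[str, list] = {}
    for rec in aln:
        if rec.cohort is not None:
            cohorts.setdefault(rec.cohort, []).append(rec)

    comparison: CohortComparison = {}
    for label in sorted(cohorts):
        records = cohorts[label]
        if not records:  # pragma: no cover - defensive
            warnings.warn(f"cohort {label!r} is empty; skipped")
            continue
        n = len(records)
        k = sum(1 for rec in records if rec.record_id in singleton_bearers)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        comparison[label] = CohortStats(
            cohort=label,
            n_records=n,
            n_with_singleton_nvlf=k,
            prevalence=k / n,
            ci95=(float(lo), float(hi)),
        )
    return comparison
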