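import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from vlfqc.alignment_io import AlignmentSet, BarcodeRecord, InputError
from vlfqc.codon_translate import translate_alignment
from vlfqc.error_and_pseudogene import (
    ErrorRateEstimate,
    SaturationError,
    compare_cohorts,
    estimate_error_rate,
    flag_pseudogene_candidates,
    k2p_distance,
    n_records_multi_from_totals,
)
from vlfqc.frequency_matrix import build_matrix
from vlfqc.vlf_analysis import classify_by_species, detect_vlfs

from conftest import build_alignment


def classified_nt(aln, threshold=0.001):
    return classify_by_species(detect_vlfs(build_matrix(aln), aln, threshold), aln)


# --- error-rate estimator -------------------------------------------------

def test_error_rate_bookkeeping():
    est = ErrorRateEstimate.from_counts(187, 10760, 216)
    assert est.rate_per_nt == 187 / (10760 * 216)
    assert est.rate_per_barcode == est.rate_per_nt * 648


def test_denominator_from_printed_totals():
    assert n_records_multi_from_totals(11333, 573) == 10760
    with pytest.raises(InputError):
        n_records_multi_from_totals(10, 11)


def test_estimator_counts_only_multi_record_species():
    # 6 records: species S (4 records, one with a codon-2 variant),
    # species U and V single records (excluded from the denominator)
    seqs = ["AGA", "AAA", "AAA", "AAA", "AAA", "AAA"]
    species = ["S", "S", "S", "S", "U", "V"]
    aln = build_alignment(seqs, species=species)
    obs = classified_nt(aln, threshold=0.25)
    est = estimate_error_rate(obs, aln)
    assert est.n_singleton_codon2 == 1
    assert est.n_records_multi == 4
    assert est.n_codon2_sites == 1


def test_estimator_invariant_to_adding_single_record_species():
    seqs = ["AGA", "AAA", "AAA", "AAA"]
    species = ["S", "S", "S", "S"]
    base = build_alignment(seqs, species=species)
    est0 = estimate_error_rate(classified_nt(base, 0.3), base)

    extra = AlignmentSet(
        records=base.records
        + [BarcodeRecord("X900", "Lonely sp", "AAA"), BarcodeRecord("X901", "Other sp", "AAA")],
    )
    est1 = estimate_error_rate(classified_nt(extra, 0.3), extra)
    assert (est0.n_singleton_codon2, est0.n_records_multi) == (
        est1.n_singleton_codon2,
        est1.n_records_multi,
    )


def test_estimator_zero_singletons_and_zero_denominator():
    aln = build_alignment(["AAA"] * 4, species=["S"] * 4)
    est = estimate_error_rate(classified_nt(aln, 0.3), aln)
    assert est.rate_per_nt == 0.0

    lonely = build_alignment(["AAA", "AAA"], species=["S", "T"])
    with pytest.raises(InputError):
        estimate_error_rate(classified_nt(lonely, 0.3), lonely)


# --- K2P ------------------------------------------------------------------

def test_k2p_identity_and_single_transition():
    seq = "ACGT" * 162
    assert k2p_distance(seq, seq) == 0.0
    mutated = "G" + seq[1:]  # one A->G transition in 648 sites
    assert round(100 * k2p_distance(seq, mutated), 2) == 0.15


def test_k2p_closed_form():
    # P = 4/40, Q = 2/40 by construction
    seq1 = "A" * 40
    seq2 = "G" * 4 + "C" * 2 + "A" * 34
    P, Q = 0.1, 0.05
    expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    assert k2p_distance(seq1, seq2) == pytest.approx(expected)


def test_k2p_pairwise_deletion_and_empty_overlap():
    # missing data on either side drops the site from both numerator and n
    assert k2p_distance("ANGT", "AAGT") == 0.0
    with pytest.raises(InputError):
        k2p_distance("NNNN", "AAAA")


def test_k2p_saturation_error_carries_site_counts():
    with pytest.raises(SaturationError) as err:
        k2p_distance("AAAA", "GGGG")
    assert err.value.n_sites == 4
    assert err.value.n_transitions == 4


@settings(derandomize=True, max_examples=50)
@given(st.tuples(st.text("ACGT", min_size=20, max_size=20),
                 st.text("ACGT", min_size=20, max_size=20)))
def test_k2p_symmetric_and_dominates_p_distance(pair):
    s1, s2 = pair
    try:
        d12 = k2p_distance(s1, s2)
    except SaturationError:
        assume(False)
    assert d12 == k2p_distance(s2, s1)
    p = sum(a != b for a, b in zip(s1, s2)) / 20
    assert d12 >= p - 1e-12
    assert (d12 == 0) == (s1 == s2)


# --- pseudogene flagging --------------------------------------------------

def _aa_classified(aln, threshold):
    proteins = translate_alignment(aln)
    return classify_by_species(
        detect_vlfs(build_matrix(proteins), aln, threshold, proteins=proteins), aln
    )


def test_flagging_threshold_is_definitional():
    # species S: two records sharing 3 amino-acid variants (codons 1-3
    # mutated at 2nd position, all amino-acid-changing) -> candidate;
    # species T: two records sharing 1 (at codon 4) -> clear
    pg = "ACAACAACAAAAAAA"  # T,T,T,K,K vs modal K,K,K,K,K
    one = "AAAAAAAAAACAAAA"  # K,K,K,T,K
    wt = "AAAAAAAAAAAAAAA"
    seqs = [pg, pg, one, one] + [wt] * 16
    species = ["S", "S", "T", "T"] + [f"B{i}" for i in range(8) for _ in (0, 1)]
    aln = build_alignment(seqs, species=species)
    aa_obs = _aa_classified(aln, threshold=0.15)
    flags = {f.record_id: f for f in flag_pseudogene_candidates(aa_obs, aln)}
    assert flags["R001"].verdict == "candidate"
    assert flags["R001"].n_shared_aavlfs == 3
    assert flags["R003"].verdict == "clear"
    assert all(f.n_shared_aavlfs >= 3 for f in flags.values() if f.verdict == "candidate")
    # corroborating evidence: stop-free, no indels, K2P to wild-type conspecific
    assert not flags["R001"].has_stop
    assert not flags["R001"].has_internal_indel
    assert flags["R001"].min_k2p_to_conspecific_nonvlf is None  # no clean conspecific


def test_flagged_candidate_reports_conspecific_divergence():
    pg = "ACAACAACAAAAAAA"
    wt = "AAAAAAAAAAAAAAA"
    seqs = [pg, pg, wt] + [wt] * 16
    species = ["S", "S", "S"] + [f"B{i}" for i in range(8) for _ in (0, 1)]
    aln = build_alignment(seqs, species=species)
    flags = flag_pseudogene_candidates(_aa_classified(aln, 0.15), aln)
    cand = [f for f in flags if f.verdict == "candidate"]
    assert len(cand) == 2
    expected = k2p_distance(pg, wt)
    for f in cand:
        assert f.min_k2p_to_conspecific_nonvlf == pytest.approx(expected)
        assert f.deeply_divergent  # 3/15 differences is way beyond 2%


def test_no_shared_aavlfs_yields_no_flags(sim_clean):
    _, aln, truth = sim_clean
    assert truth.pseudogene_records == {}
    aa_obs = _aa_classified(aln, threshold=0.001)
    assert all(
        f.verdict == "clear" for f in flag_pseudogene_candidates(aa_obs, aln)
    )


# --- cohort comparison ----------------------------------------------------

def test_cohort_edge_cases():
    seqs = ["AAA"] * 4 + ["AAA"]
    aln = build_alignment(
        seqs, species=["S"] * 4 + ["T"], cohorts=["early"] * 4 + ["late"]
    )
    comparison = compare_cohorts(aln, classified_nt(aln, 0.3))
    early = comparison["early"]
    assert early.prevalence == 0.0
    assert early.ci95[0] == 0.0
    late = comparison["late"]  # single-record cohort: prevalence in {0, 1}, wide CI
    assert late.prevalence in (0.0, 1.0)
    assert late.ci95[1] - late.ci95[0] > 0.5
    for stats in comparison.values():
        assert stats.ci95[0] <= stats.prevalence <= stats.ci95[1]
        assert 0.0 <= stats.ci95[0] <= stats.ci95[1] <= 1.0


def test_cohort_prevalence_ordering_recovered():
    """Two simulated cohorts with per-record error means 0.3 vs 0.05 separate."""
    from vlfqc.alignment_io import concatenate
    from vlfqc.synthetic_data import SimulationSpec, generate

    def cohort(label, per_record_errors, seed):
        spec = SimulationSpec(
            n_species=250, mean_records_per_species=4.0,
            error_rate=per_record_errors / 648, seed=seed,
            cohort=label, species_prefix=f"Sp{label}", record_prefix=label,
        )
        return generate(spec)[0]

    merged = concatenate([cohort("A", 0.3, 21), cohort("B", 0.05, 22)])
    assert len(merged) >= 1800
    obs = classified_nt(merged, threshold=0.005)
    comparison = compare_cohorts(merged, obs)
    a, b = comparison["A"], comparison["B"]
    assert a.prevalence > b.prevalence
    assert a.ci95[0] > b.ci95[1]  # disjoint confidence intervals
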