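from collections import Counter

import pytest

from vlfqc.alignment_io import AlignmentSet, InputError
from vlfqc.codon_translate import translate_alignment
from vlfqc.frequency_matrix import build_matrix
from vlfqc.vlf_analysis import (
    INDETERMINATE,
    SHARED,
    SINGLETON,
    classify_by_species,
    concordance,
    detect_vlfs,
    mean_per_sequence,
    positional_histogram,
    sliding_window_profile,
    terminal_enrichment,
)

from conftest import build_alignment


def detect_and_classify(aln, threshold=0.001):
    fm = build_matrix(aln)
    return classify_by_species(detect_vlfs(fm, aln, threshold=threshold), aln)


def test_detection_threshold_is_strict():
    # 1 carrier of 2000 (0.05%) is a VLF; 3 of 2000 (0.15%) is not
    one = build_alignment(["AAA"] * 1999 + ["GAA"])
    obs = detect_vlfs(build_matrix(one), one)
    assert len(obs) == 1
    assert (obs[0].position, obs[0].residue, obs[0].codon_class) == (1, "G", 1)

    three = build_alignment(["AAA"] * 1997 + ["GAA"] * 3)
    assert detect_vlfs(build_matrix(three), three) == []


def test_modal_residue_never_emitted_even_if_rare():
    # two records, modal1 frac 0.5: nothing is below any sane cut, and even
    # at a degenerate 60% cut the modal residue itself must not be emitted
    aln = build_alignment(["AAA", "GAA"])
    obs = detect_vlfs(build_matrix(aln), aln, threshold=0.6)
    assert all(o.residue != "A" or o.position != 1 for o in obs)
    assert {o.residue for o in obs if o.position == 1} == {"G"}


@pytest.mark.parametrize("bad", [0, 1, 1.5, -0.1])
def test_threshold_domain(bad):
    aln = build_alignment(["AAA", "AAA"])
    with pytest.raises(InputError):
        detect_vlfs(build_matrix(aln), aln, threshold=bad)


def test_classification_by_species():
    # 10 records; species S carries G at position 1 in both its records ->
    # shared; species T has one of five records with C at position 2 ->
    # singleton; species U (single record) carries T at position 3 ->
    # indeterminate
    seqs = (
        ["GAA", "GAA"]                      # species S
        + ["ACA", "AAA", "AAA", "AAA", "AAA"]  # species T
        + ["AAT"]                           # species U
        + ["AAA", "AAA"]                    # species V (background)
    )
    species = ["S", "S", "T", "T", "T", "T", "T", "U", "V", "V"]
    aln = build_alignment(seqs, species=species)
    obs = detect_and_classify(aln, threshold=0.25)
    by_key = {(o.species, o.position, o.residue): o.status for o in obs}
    assert by_key[("S", 1, "G")] == SHARED
    assert by_key[("T", 2, "C")] == SINGLETON
    assert by_key[("U", 3, "T")] == INDETERMINATE


def test_shared_status_is_residue_specific():
    # two conspecific records with DIFFERENT rare residues at one position
    # are two singletons, not a shared variant
    seqs = ["GAA", "CAA"] + ["AAA"] * 8
    aln = build_alignment(seqs, species=["S", "S"] + [f"B{i}" for i in range(8)])
    obs = detect_and_classify(aln, threshold=0.25)
    statuses = [o.status for o in obs if o.position == 1]
    assert statuses == [SINGLETON, SINGLETON]


def test_status_partition_and_order_invariance(sim_small):
    _, aln, _ = sim_small
    obs = detect_and_classify(aln, threshold=0.01)
    assert all(o.status in (SINGLETON, SHARED, INDETERMINATE) for o in obs)
    assert all(o.column_frac < 0.01 for o in obs)

    reversed_aln = AlignmentSet(
        records=list(reversed(aln.records)), frame_offset=aln.frame_offset
    )
    obs_rev = detect_and_classify(reversed_aln, threshold=0.01)
    key = lambda o: (o.record_id, o.position, o.residue, o.status)
    assert sorted(map(key, obs)) == sorted(map(key, obs_rev))


def test_mean_per_sequence_rounds_half_up():
    assert mean_per_sequence(494, 347) == 1.4
    assert mean_per_sequence(40, 13) == 3.1
    assert mean_per_sequence(274, 202) == 1.4  # 1.36 rounds up, not truncates
    assert mean_per_sequence(0, 0) == 0.0


def test_concordance_counts_synonymous_variant_as_nt_only():
    # record R001 carries AAG at its first codon: modal AAA is Lys, AAG is
    # Lys too -> an nVLF with no aaVLF
    seqs = ["AAG"] + ["AAA"] * 9
    species = ["S", "S"] + [f"B{i}" for i in range(8)]
    aln = build_alignment(seqs, species=species)
    proteins = translate_alignment(aln)
    nt_obs = detect_and_classify(aln, threshold=0.25)
    aa_obs = classify_by_species(
        detect_vlfs(build_matrix(proteins), aln, threshold=0.25, proteins=proteins),
        aln,
    )
    table = concordance(nt_obs, aa_obs)
    row = table[SINGLETON]
    assert (row.nt_vlfs, row.nt_seqs, row.nt_mean) == (1, 1, 1.0)
    assert (row.nt_only, row.aa_only, row.both) == (1, 0, 0)


def test_concordance_pseudogene_subset_restricts_shared_vlfs():
    seqs = ["GAA", "GAA"] + ["AAA"] * 8
    species = ["S", "S"] + [f"B{i}" for i in range(8)]
    aln = build_alignment(seqs, species=species)
    nt_obs = detect_and_classify(aln, threshold=0.25)
    table = concordance(nt_obs, [], pseudogene_ids={"R001", "R002"})
    assert table["pseudogene"].nt_vlfs == 2
    assert table[SHARED].nt_vlfs == 2


def test_histogram_bins_tile_the_segment(sim_small):
    _, aln, _ = sim_small
    obs = detect_and_classify(aln, threshold=0.01)
    profile = positional_histogram(obs, bin_width=50, length=aln.length)
    assert len(profile.starts) == 13  # 648 = 12*50 + truncated 48-wide bin
    for status, counts in profile.counts.items():
        assert counts.sum() == profile.total(status)

    empty = positional_histogram([], bin_width=50, length=648)
    assert empty.total() == 0


def test_single_observation_covered_by_exactly_window_windows():
    from vlfqc.vlf_analysis import VariantObservation

    obs = [
        VariantObservation(
            record_id="r", species="s", position=40, residue="G",
            column_frac=0.0005, alphabet="nt", codon_class=1, status=SINGLETON,
        )
    ]
    profile = sliding_window_profile(obs, window=30, length=648)
    counts = profile.counts[SINGLETON]
    assert len(counts) == 648 - 30 + 1
    assert counts.sum() == 30
    covered = [s for s, c in zip(profile.starts, counts) if c == 1]
    assert covered == list(range(11, 41))

    empty = sliding_window_profile([], window=30, length=648)
    assert empty.counts == {}


def test_terminal_enrichment_ratio():
    from vlfqc.vlf_analysis import VariantObservation

    def obs_at(positions):
        return [
            VariantObservation(
                record_id=f"r{i}", species="s", position=p, residue="G",
                column_frac=0.0005, alphabet="nt", codon_class=1, status=SINGLETON,
            )
            for i, p in enumerate(positions)
        ]

    uniform = positional_histogram(obs_at(range(1, 649)), length=648)
    assert terminal_enrichment(uniform, 100) == pytest.approx(1.0)

    terminal = positional_histogram(obs_at(range(1, 51)), length=648)
    assert terminal_enrichment(terminal, 100) == pytest.approx(648 / 200)

    import math
    assert math.isnan(terminal_enrichment(positional_histogram([], length=648), 100))
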