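import pytest

from vlfqc.alignment_io import AlignmentSet, BarcodeRecord
from vlfqc.synthetic_data import SimulationSpec, generate


def build_alignment(seqs, species=None, cohorts=None, frame_offset=0):
    """Construct an AlignmentSet from bare sequences with default labels."""
    n = len(seqs)
    species = species or [f"Sp{i + 1}" for i in range(n)]
    cohorts = cohorts or [None] * n
    records = [
        BarcodeRecord(
            record_id=f"R{i + 1:03d}", species=species[i], sequence=seqs[i],
            cohort=cohorts[i],
        )
        for i in range(n)
    ]
    return AlignmentSet(records=records, frame_offset=frame_offset)


@pytest.fixture(scope="session")
def sim_small():
    """A small error-bearing simulation shared across tests: (spec, aln, truth)."""
    spec = SimulationSpec(
        n_species=40, mean_records_per_species=3.0, error_rate=2e-4, seed=7
    )
    aln, truth = generate(spec)
    return spec, aln, truth


@pytest.fixture(scope="session")
def sim_clean():
    """An error-free, pseudogene-free simulation: (spec, aln, truth)."""
    spec = SimulationSpec(
        n_species=40, mean_records_per_species=3.0, error_rate=0.0, seed=11
    )
    aln, truth = generate(spec)
    return spec, aln, truth
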