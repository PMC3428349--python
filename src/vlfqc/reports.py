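"""End-to-end orchestration and table-shaped TSV reports.

``run_full`` executes the whole QC pipeline on one alignment — frequency
matrices, modal comparisons, VLF detection/classification, concordance,
spatial profiles, error-rate estimate, pseudogene flags, optional cohort
comparison — and writes one TSV per report.  Every file starts with comment
lines carrying the package version and the configuration, so each number in
the summaries can be re-derived from the exported observation tables.

Outputs are deterministic given input + config: stable sort orders
everywhere, no timestamps.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from ._util import round_half_up
from .alignment_io import AlignmentSet, InputError, read_alignment, trim_to_barcode
from .codon_translate import GeneticCode, translate_alignment
from .error_and_pseudogene import (
    CohortComparison,
    ErrorRateEstimate,
    PseudogeneFlag,
    compare_cohorts,
    estimate_error_rate,
    flag_pseudogene_candidates,
)
from .frequency_matrix import (
    FrequencyMatrix,
    build_matrix,
    codon_class_variance_ratio,
    conservation_summary,
    count_differences,
    modal_sequence,
)
from .vlf_analysis import (
    classify_by_species,
    concordance,
    detect_vlfs,
    positional_histogram,
    sliding_window_profile,
    terminal_enrichment,
)

logger = logging.getLogger("vlfqc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through TOML."""

    input: str
    outdir: str
    threshold: float = 0.001
    window: int = 30
    bin_width: int = 50
    terminal_span: int = 100
    pseudogene_threshold: int = 3
    genetic_code: int = 2
    species_pattern: Optional[str] = None
    cohort_pattern: Optional[str] = None
    trim_start: Optional[int] = None
    trim_length: Optional[int] = None
    frame_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise InputError("threshold must lie in (0, 1)")
        if self.window < 1 or self.bin_width < 1 or self.terminal_span < 1:
            raise InputError("window, bin_width and terminal_span must be positive")
        if self.pseudogene_threshold < 1:
            raise InputError("pseudogene_threshold must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if value is None:
                    continue
                if isinstance(value, str):
                    if "'" in value:  # basic string with escapes
                        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
                        fh.write(f'{f.name} = "{escaped}"\n')
                    else:  # literal string: regexes survive verbatim
                        fh.write(f"{f.name} = '{value}'\n")
                else:
                    fh.write(f"{f.name} = {value}\n")

    def header_items(self) -> list[tuple[str, object]]:
        return [
            (f.name, getattr(self, f.name))
            for f in dataclasses.fields(self)
            if getattr(self, f.name) is not None
        ]


def _write_tsv(df: pd.DataFrame, path: Path, config: Optional[RunConfig]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vlfqc {__version__}\n")
        if config is not None:
            for key, value in config.header_items():
                fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def matrix_frame(fm: FrequencyMatrix) -> pd.DataFrame:
    """Wide per-position table: residue fractions plus modal columns."""
    residues = sorted({res for col in fm for res in col.counts})
    rows = []
    for col in fm:
        row: dict = {"position": col.position, "n_scored": col.n_scored}
        for res in residues:
            row[f"frac_{res}"] = (
                col.counts.get(res, 0) / col.n_scored if col.n_scored else 0.0
            )
        row.update(
            modal1=col.modal1 or "",
            modal1_frac=col.modal1_frac,
            modal2=col.modal2 or "",
            modal2_frac=col.modal2_frac,
            tie=col.tie,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def observations_frame(observations) -> pd.DataFrame:
    rows = [
        {
            "record_id": o.record_id,
            "species": o.species,
            "position": o.position,
            "residue": o.residue,
            "frac": o.column_frac,
            "alphabet": o.alphabet,
            "codon_class": "" if o.codon_class is None else o.codon_class,
            "status": o.status or "",
        }
        for o in observations
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "species",
            "position",
            "residue",
            "frac",
            "alphabet",
            "codon_class",
            "status",
        ],
    )
    return df.sort_values(["alphabet", "position", "record_id", "residue"]).reset_index(
        drop=True
    )


def conservation_frame(summaries: dict) -> pd.DataFrame:
    rows = []
    for label, cc in summaries.items():
        p100, p1, p12 = cc.percentages()
        rows.append(
            {
                "class": label,
                "n_sites": cc.n_sites,
                "modal1_100": cc.n_fully_conserved,
                "modal1_100_pct": p100,
                "modal1_gt999": cc.n_modal1_above,
                "modal1_gt999_pct": p1,
                "modal12_gt999": cc.n_modal12_above,
                "modal12_gt999_pct": p12,
                "mean_diffs_vs_modal1": round_half_up(cc.mean_diffs, 1),
                "diffs_min": cc.diffs_min,
                "diffs_max": cc.diffs_max,
            }
        )
    return pd.DataFrame(rows)


def concordance_frame(table) -> pd.DataFrame:
    rows = []
    for status, r in table.items():
        rows.append(
            {
                "status": status,
                "nt_vlfs": r.nt_vlfs,
                "nt_seqs": r.nt_seqs,
                "nt_mean": r.nt_mean,
                "nt_min": r.nt_range[0],
                "nt_max": r.nt_range[1],
                "aa_vlfs": r.aa_vlfs,
                "aa_seqs": r.aa_seqs,
                "aa_mean": r.aa_mean,
                "aa_min": r.aa_range[0],
                "aa_max": r.aa_range[1],
                "nt_only": r.nt_only,
                "aa_only": r.aa_only,
                "both": r.both,
            }
        )
    return pd.DataFrame(rows)


def flags_frame(flags: list[PseudogeneFlag]) -> pd.DataFrame:
    rows = [
        {
            "record_id": f.record_id,
            "species": f.species,
            "n_shared_aavlfs": f.n_shared_aavlfs,
            "has_stop": f.has_stop,
            "has_internal_indel": f.has_internal_indel,
            "has_frameshift_indel": f.has_frameshift_indel,
            "min_k2p_to_conspecific": (
                "" if f.min_k2p_to_conspecific_nonvlf is None
                else round(f.min_k2p_to_conspecific_nonvlf, 6)
            ),
            "verdict": f.verdict,
        }
        for f in flags
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "species",
            "n_shared_aavlfs",
            "has_stop",
            "has_internal_indel",
            "has_frameshift_indel",
            "min_k2p_to_conspecific",
            "verdict",
        ],
    )


def cohorts_frame(comparison: CohortComparison) -> pd.DataFrame:
    rows = [
        {
            "cohort": c.cohort,
            "n_records": c.n_records,
            "n_with_singleton_nvlf": c.n_with_singleton_nvlf,
            "prevalence": c.prevalence,
            "ci95_low": c.ci95[0],
            "ci95_high": c.ci95[1],
        }
        for c in comparison.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cohort",
            "n_records",
            "n_with_singleton_nvlf",
            "prevalence",
            "ci95_low",
            "ci95_high",
        ],
    )


def spatial_frame(profile, alphabet: str) -> pd.DataFrame:
    statuses = sorted(profile.counts)
    rows = []
    for i, start in enumerate(profile.starts):
        row = {"alphabet": alphabet, "start": start}
        if profile.kind == "histogram":
            row["end"] = min(start + profile.bin_or_window - 1, profile.length)
        else:
            row["end"] = start + profile.bin_or_window - 1
        for status in statuses:
            row[status] = int(profile.counts[status][i])
        rows.append(row)
    return pd.DataFrame(rows)


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle; returns results.

    Report files written to ``config.outdir``: nt and aa frequency matrices,
    observation tables, conservation summary, VLF/concordance summary,
    spatial profiles, error-rate report, pseudogene flags, and (when cohort
    labels are present) the cohort comparison.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: %s", config.input)
    aln = read_alignment(
        config.input,
        species_pattern=config.species_pattern,
        cohort_pattern=config.cohort_pattern,
    )
    if config.trim_start is not None and config.trim_length is not None:
        logger.info(
            "stage trim: start=%d length=%d", config.trim_start, config.trim_length
        )
        aln = trim_to_barcode(
            aln, config.trim_start, config.trim_length, frame_offset=config.frame_offset
        )
    else:
        aln.frame_offset = config.frame_offset
    logger.info(
        "stage counts: %d records, %d species", len(aln), len(aln.species_counts())
    )

    code = GeneticCode.from_ncbi_id(config.genetic_code)
    nt_fm = build_matrix(aln)
    proteins = translate_alignment(aln, code)
    aa_fm = build_matrix(proteins)
    logger.info("stage matrix: %d nt columns, %d aa columns", nt_fm.length, aa_fm.length)

    nt_modal = modal_sequence(nt_fm)
    aa_modal = modal_sequence(aa_fm)
    nt_diffs = [
        count_differences(rec.sequence, nt_modal, aln.frame_offset) for rec in aln
    ]
    aa_diffs = [
        count_differences(p.residues, aa_modal, alphabet="aa") for p in proteins
    ]
    summary = conservation_summary(nt_fm, nt_diffs)
    summary.update(conservation_summary(aa_fm, aa_diffs))

    nt_obs = classify_by_species(
        detect_vlfs(nt_fm, aln, threshold=config.threshold), aln
    )
    aa_obs = classify_by_species(
        detect_vlfs(aa_fm, aln, threshold=config.threshold, proteins=proteins), aln
    )
    logger.info("stage vlf: %d nt, %d aa observations", len(nt_obs), len(aa_obs))

    flags = flag_pseudogene_candidates(
        aa_obs, aln, threshold=config.pseudogene_threshold, code=code
    )
    candidate_ids = {f.record_id for f in flags if f.verdict == "candidate"}
    table = concordance(nt_obs, aa_obs, pseudogene_ids=candidate_ids)

    histogram = positional_histogram(nt_obs, bin_width=config.bin_width, length=aln.length)
    window = sliding_window_profile(nt_obs, window=config.window, length=aln.length)
    aa_hist = positional_histogram(
        aa_obs, bin_width=max(1, config.bin_width // 3), length=aa_fm.length
    )

    error = estimate_error_rate(nt_obs, aln)
    logger.info(
        "stage error-rate: %d/%d*%d -> %.3g /nt",
        error.n_singleton_codon2,
        error.n_records_multi,
        error.n_codon2_sites,
        error.rate_per_nt,
    )

    cohort_labels = {rec.cohort for rec in aln if rec.cohort is not None}
    cohorts = compare_cohorts(aln, nt_obs) if cohort_labels else {}

    _write_tsv(matrix_frame(nt_fm), outdir / "matrix_nt.tsv", config)
    _write_tsv(matrix_frame(aa_fm), outdir / "matrix_aa.tsv", config)
    _write_tsv(observations_frame(nt_obs + aa_obs), outdir / "observations.tsv", config)
    _write_tsv(conservation_frame(summary), outdir / "conservation.tsv", config)
    _write_tsv(concordance_frame(table), outdir / "vlf_summary.tsv", config)
    _write_tsv(
        pd.concat(
            [spatial_frame(histogram, "nt"), spatial_frame(aa_hist, "aa")],
            ignore_index=True,
        ),
        outdir / "spatial_histogram.tsv",
        config,
    )
    _write_tsv(spatial_frame(window, "nt"), outdir / "sliding_window.tsv", config)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "n_singleton_codon2": error.n_singleton_codon2,
                    "n_records_multi": error.n_records_multi,
                    "n_codon2_sites": error.n_codon2_sites,
                    "rate_per_nt": error.rate_per_nt,
                    "rate_per_barcode": error.rate_per_barcode,
                }
            ]
        ),
        outdir / "error_rate.tsv",
        config,
    )
    _write_tsv(flags_frame(flags), outdir / "pseudogene_flags.tsv", config)
    if cohorts:
        _write_tsv(cohorts_frame(cohorts), outdir / "cohorts.tsv", config)

    try:
        variance_ratio = codon_class_variance_ratio(summary)
    except InputError:
        variance_ratio = None

    return {
        "alignment": aln,
        "variance_ratio": variance_ratio,
        "nt_matrix": nt_fm,
        "aa_matrix": aa_fm,
        "conservation": summary,
        "nt_observations": nt_obs,
        "aa_observations": aa_obs,
        "concordance": table,
        "histogram": histogram,
        "sliding_window": window,
        "error_rate": error,
        "pseudogene_flags": flags,
        "cohorts": cohorts,
        "terminal_enrichment": {
            status: terminal_enrichment(histogram, config.terminal_span, status)
            for status in histogram.positions
        },
    }
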