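"""Synthetic barcode alignments with known ground truth.

The generator emulates the structure a frequency matrix sees in a large
multi-species barcode alignment, so that every analytic stage has an offline
oracle:

* a stop-free ancestral ("base modal") sequence of in-frame codons;
* species haplotypes varying through two channels — *common binary
  polymorphism* (an alternative allele at a column, shared across many
  species, as real alignments show "mostly binary" variation) and *rare
  species-private variants* (the biological source of shared VLFs).  Each
  channel respects the codon-class conservation hierarchy (2nd < 1st << 3rd);
* records that copy their species haplotype and then receive Poisson-thinned
  substitution errors, optionally concentrated in the terminal spans
  (emulating Sanger read-quality decay at the segment ends);
* optional co-amplified cryptic pseudogene species: a subset of conspecific
  records carry an engineered haplotype with several shared amino-acid
  changes plus extra (mostly silent) divergence, stop-free by construction.

Two structural guarantees make exact oracles possible: every haplotype is
stop-free under the vertebrate mitochondrial code, and the ancestral base is
enforced to stay *strictly modal* at every column (record-weighted), so the
1st modal sequence of an error-free simulation equals ``base_modal`` exactly.

What the generator does **not** model: phylogenetic correlation between
species (haplotypes are drawn independently from the base), indels outside
the pseudogene option, and ambiguity codes / partial reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment_io import AlignmentSet, BarcodeRecord, VlfqcError
from .codon_translate import GeneticCode, STOP, VERTEBRATE_MITO

BASES = "ACGT"


class SimulationSpecError(VlfqcError, ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass
class SimulationSpec:
    """Parameters of one simulated study.

    Defaults emulate the conditions of a large avian barcode survey at desk
    scale: 300 species averaging 4 records each (geometric sizes, floor 1),
    648 in-frame nucleotides, per-site haplotype diversity per codon class
    taken from the observed mean differences vs the modal sequence divided by
    216 sites (0.026 / 0.002 / 0.33), an 8e-5 errors/nt Sanger miscall rate
    with 70% of errors forced into the two 100-nt terminal spans, and no
    pseudogenes unless requested.
    """

    n_species: int = 300
    mean_records_per_species: float = 4.0
    length: int = 648
    codon1_diversity: float = 0.026
    codon2_diversity: float = 0.002
    codon3_diversity: float = 0.33
    codon1_private_rate: float = 0.02
    codon2_private_rate: float = 0.01
    codon3_private_rate: float = 0.02
    error_rate: float = 8e-5
    terminal_bias: float = 0.7
    terminal_span: int = 100
    n_pseudogene_species: int = 0
    pseudogene_aa_changes: int = 4
    pseudogene_carriers: int = 2
    pseudogene_divergence: float = 0.12
    pseudogene_indel_length: int = 0
    cohort: Optional[str] = None
    species_prefix: str = "Species"
    record_prefix: str = "REC"
    seed: int = 0

    def validate(self) -> None:
        n_codons = self.length // 3
        if self.n_species < 1:
            raise SimulationSpecError("n_species must be >= 1")
        if self.length < 3 or self.length % 3:
            raise SimulationSpecError("length must be a positive multiple of 3")
        if self.mean_records_per_species < 1:
            raise SimulationSpecError("mean_records_per_species must be >= 1")
        for name in (
            "codon1_diversity",
            "codon2_diversity",
            "codon3_diversity",
        ):
            d = getattr(self, name)
            # 0.36 cap: the binary-polymorphism channel keeps minor allele
            # frequencies below 0.5 so the ancestral base stays modal
            if not (0 <= d <= 0.36):
                raise SimulationSpecError(f"{name} must lie in [0, 0.36]")
        for name in (
            "codon1_private_rate",
            "codon2_private_rate",
            "codon3_private_rate",
            "error_rate",
            "terminal_bias",
            "pseudogene_divergence",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationSpecError(f"{name} must lie in [0, 1]")
        if not (1 <= self.terminal_span <= self.length // 2):
            raise SimulationSpecError("terminal_span must lie in [1, length/2]")
        if self.n_pseudogene_species < 0 or self.n_pseudogene_species > self.n_species:
            raise SimulationSpecError("n_pseudogene_species out of range")
        if self.n_pseudogene_species:
            if self.pseudogene_carriers < 2:
                raise SimulationSpecError("pseudogene_carriers must be >= 2")
            if not (1 <= self.pseudogene_aa_changes <= n_codons):
                raise SimulationSpecError("pseudogene_aa_changes out of range")
        if self.pseudogene_indel_length < 0:
            raise SimulationSpecError("pseudogene_indel_length must be >= 0")


@dataclass(frozen=True)
class InjectedError:
    record_id: str
    position: int  # 1-based
    from_base: str
    to_base: str


@dataclass
class GroundTruth:
    """The simulator's record of what it injected, keyed for recovery tests."""

    base_modal: str
    species_haplotypes: dict[str, str]
    injected_errors: list[InjectedError] = field(default_factory=list)
    pseudogene_records: dict[str, list[int]] = field(default_factory=dict)
    pseudogene_indels: dict[str, list[int]] = field(default_factory=dict)

    def error_positions(self) -> set[tuple[str, int]]:
        return {(e.record_id, e.position) for e in self.injected_errors}


def _nonstop_codons(code: GeneticCode) -> list[str]:
    return sorted(c for c, aa in code.table.items() if aa != STOP)


def _repair_stops(hap: np.ndarray, base: np.ndarray, code: GeneticCode) -> None:
    """Revert substituted bases toward the ancestral codon until stop-free."""
    n_codons = hap.size // 3
    for c in range(n_codons):
        codon = hap[3 * c : 3 * c + 3]
        while "".join(codon) in code.stop_codons:
            for k in (2, 1, 0):
                if codon[k] != base[3 * c + k]:
                    codon[k] = base[3 * c + k]
                    break
            else:  # pragma: no cover - ancestral codons are stop-free
                break


def generate(
    spec: SimulationSpec, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[AlignmentSet, GroundTruth]:
    """Draw one alignment + ground truth; byte-deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    n_codons = L // 3
    nonstop = _nonstop_codons(code)

    # ancestral sequence: in-frame, stop-free codons
    base_codons = [nonstop[i] for i in rng.integers(0, len(nonstop), n_codons)]
    base = np.array(list("".join(base_codons)), dtype="<U1")
    base_modal = "".join(base)

    diversities = {
        1: spec.codon1_diversity,
        2: spec.codon2_diversity,
        3: spec.codon3_diversity,
    }
    private_rates = {
        1: spec.codon1_private_rate,
        2: spec.codon2_private_rate,
        3: spec.codon3_private_rate,
    }

    def stop_safe_alternatives(j: int, current: np.ndarray) -> list[str]:
        """Bases != current[j] that keep codon j//3 (with current context) non-stop."""
        c = j // 3
        codon = list(current[3 * c : 3 * c + 3])
        out = []
        for b in BASES:
            if b == current[j]:
                continue
            codon[j % 3] = b
            if "".join(codon) not in code.stop_codons:
                out.append(b)
        return out

    # common binary polymorphism: column -> (minor allele frequency, alt base)
    polymorphic: list[tuple[int, float, str]] = []
    for j in range(L):
        d = diversities[j % 3 + 1]
        if d <= 0:
            continue
        if d < 0.25:
            if rng.random() >= d / 0.25:
                continue
            q = rng.uniform(0.05, 0.45)
        else:
            q = rng.uniform(d - 0.12, d + 0.12)
        alts = stop_safe_alternatives(j, base)
        if not alts:  # pragma: no cover - always >=1 stop-safe alternative
            continue
        polymorphic.append((j, q, alts[rng.integers(len(alts))]))

    # species sizes: geometric with floor 1, mean as specified
    sizes = rng.geometric(1.0 / spec.mean_records_per_species, spec.n_species).astype(int)
    pg_species_idx = sorted(
        rng.choice(spec.n_species, spec.n_pseudogene_species, replace=False).tolist()
    )
    for s in pg_species_idx:
        sizes[s] = max(sizes[s], spec.pseudogene_carriers)
    species_names = [
        f"{spec.species_prefix}_{s + 1:04d}" for s in range(spec.n_species)
    ]

    # haplotypes: tile the base, apply common alleles, then private variants
    haps = np.tile(base, (spec.n_species, 1))
    for j, q, alt in polymorphic:
        mask = rng.random(spec.n_species) < q
        haps[mask, j] = alt
    class_columns = {k: np.arange(k - 1, L, 3) for k in (1, 2, 3)}
    for s in range(spec.n_species):
        for k in (1, 2, 3):
            n_priv = rng.poisson(private_rates[k])
            if not n_priv:
                continue
            cols = rng.choice(class_columns[k], min(n_priv, n_codons), replace=False)
            for j in sorted(int(c) for c in cols):
                choices = [b for b in BASES if b != haps[s, j] and b != base[j]]
                if choices:
                    haps[s, j] = choices[rng.integers(len(choices))]
    for s in range(spec.n_species):
        _repair_stops(haps[s], base, code)

    # enforce strict modal dominance of the ancestral base at every column
    # (record-weighted), then re-repair: both steps only move bases toward
    # the ancestral state, so one extra pass converges
    for j in range(L):
        col = haps[:, j]
        if (col == base[j]).all():
            continue
        while True:
            residues, idx = np.unique(col, return_inverse=True)
            weights = np.bincount(idx, weights=sizes)
            base_w = weights[list(residues).index(base[j])] if base[j] in residues else 0
            order = np.argsort(-weights)
            top = residues[order[0]]
            if top == base[j] and (len(residues) == 1 or weights[order[1]] < base_w):
                break
            rival = top if top != base[j] else residues[order[1]]
            carriers = np.flatnonzero(col == rival)
            flip = carriers[np.argmax(sizes[carriers])]
            col[flip] = base[j]
    for s in range(spec.n_species):
        _repair_stops(haps[s], base, code)

    truth = GroundTruth(
        base_modal=base_modal,
        species_haplotypes={
            species_names[s]: "".join(haps[s]) for s in range(spec.n_species)
        },
    )

    # engineered pseudogene haplotypes (stop-free by construction)
    pg_haplotypes: dict[int, tuple[np.ndarray, list[int], list[int]]] = {}
    for s in pg_species_idx:
        pg = haps[s].copy()
        engineered: list[int] = []
        for c in rng.permutation(n_codons):
            if len(engineered) == spec.pseudogene_aa_changes:
                break
            c = int(c)
            j = 3 * c + 1  # second codon position: reliably amino-acid-changing
            codon = "".join(pg[3 * c : 3 * c + 3])
            if "-" in codon:
                continue
            candidates = []
            for b in BASES:
                if b == pg[j]:
                    continue
                new = codon[0] + b + codon[2]
                if code.table[new] != STOP and code.table[new] != code.table[codon]:
                    candidates.append(b)
            if not candidates:
                continue
            pg[j] = candidates[rng.integers(len(candidates))]
            engineered.append(j + 1)
        # extra divergence, 70% at 3rd positions (mostly silent), rest at 1st
        n_extra = max(0, int(round(spec.pseudogene_divergence * L)) - len(engineered))
        n3 = int(round(0.7 * n_extra))
        for k, n_k in ((3, n3), (1, n_extra - n3)):
            cols = rng.choice(class_columns[k], min(n_k, n_codons), replace=False)
            for j in sorted(int(c) for c in cols):
                alts = stop_safe_alternatives(j, pg)
                if alts:
                    pg[j] = alts[rng.integers(len(alts))]
        indel_positions: list[int] = []
        if spec.pseudogene_indel_length:
            ln = spec.pseudogene_indel_length
            start = int(rng.integers(spec.terminal_span, L - spec.terminal_span - ln))
            pg[start : start + ln] = "-"
            indel_positions = list(range(start + 1, start + ln + 1))
        _repair_stops(pg, base, code)
        pg_haplotypes[s] = (pg, sorted(engineered), indel_positions)

    # records: copy haplotype, then Poisson-thinned terminal-biased errors
    terminal_positions = np.concatenate(
        [np.arange(spec.terminal_span), np.arange(L - spec.terminal_span, L)]
    )
    records: list[BarcodeRecord] = []
    counter = 0
    for s in range(spec.n_species):
        for r in range(sizes[s]):
            counter += 1
            rid = f"{spec.record_prefix}{counter:05d}"
            if s in pg_haplotypes and r < spec.pseudogene_carriers:
                pg, engineered, indels = pg_haplotypes[s]
                seq = pg.copy()
                truth.pseudogene_records[rid] = list(engineered)
                if indels:
                    truth.pseudogene_indels[rid] = list(indels)
            else:
                seq = haps[s].copy()
            n_err = rng.poisson(spec.error_rate * L)
            used: set[int] = set()
            for _ in range(n_err):
                for _attempt in range(100):
                    if rng.random() < spec.terminal_bias:
                        pos = int(terminal_positions[rng.integers(terminal_positions.size)])
                    else:
                        pos = int(rng.integers(L))
                    if pos not in used and seq[pos] != "-":
                        break
                else:  # pragma: no cover
                    continue
                used.add(pos)
                alts = [b for b in BASES if b != seq[pos]]
                to = alts[rng.integers(3)]
                truth.injected_errors.append(
                    InjectedError(rid, pos + 1, str(seq[pos]), to)
                )
                seq[pos] = to
            records.append(
                BarcodeRecord(
                    record_id=rid,
                    species=species_names[s],
                    sequence="".join(seq),
                    cohort=spec.cohort,
                )
            )

    # the "cryptic" property, asserted on the un-errored haplotypes
    for s, (pg, _, _) in pg_haplotypes.items():
        for c in range(n_codons):
            codon = "".join(pg[3 * c : 3 * c + 3])
            assert "-" in codon or codon not in code.stop_codons, (
                f"pseudogene haplotype of species {s} contains stop {codon}"
            )

    return AlignmentSet(records=records, frame_offset=0), truth


# ---------------------------------------------------------------------------
# ground-truth serialisation (plain TSV, round-trippable)

def write_ground_truth(truth: GroundTruth, prefix) -> dict[str, Path]:
    """Write machine-readable truth tables; returns the paths written."""
    prefix = Path(prefix)
    paths = {
        "errors": prefix.with_suffix(".errors.tsv"),
        "pseudogenes": prefix.with_suffix(".pseudogenes.tsv"),
        "haplotypes": prefix.with_suffix(".haplotypes.tsv"),
        "modal": prefix.with_suffix(".modal.tsv"),
    }
    with open(paths["errors"], "w") as fh:
        fh.write("record_id\tposition\tfrom_base\tto_base\n")
        for e in truth.injected_errors:
            fh.write(f"{e.record_id}\t{e.position}\t{e.from_base}\t{e.to_base}\n")
    with open(paths["pseudogenes"], "w") as fh:
        fh.write("record_id\taa_change_positions\tindel_positions\n")
        for rid in sorted(truth.pseudogene_records):
            subs = ",".join(map(str, truth.pseudogene_records[rid]))
            indels = ",".join(map(str, truth.pseudogene_indels.get(rid, [])))
            fh.write(f"{rid}\t{subs}\t{indels}\n")
    with open(paths["haplotypes"], "w") as fh:
        fh.write("species\tsequence\n")
        for sp in sorted(truth.species_haplotypes):
            fh.write(f"{sp}\t{truth.species_haplotypes[sp]}\n")
    with open(paths["modal"], "w") as fh:
        fh.write("base_modal\n")
        fh.write(truth.base_modal + "\n")
    return paths


def read_ground_truth(prefix) -> GroundTruth:
    """Inverse of :func:`write_ground_truth`."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".modal.tsv")) as fh:
        fh.readline()
        base_modal = fh.readline().strip()
    haplotypes: dict[str, str] = {}
    with open(prefix.with_suffix(".haplotypes.tsv")) as fh:
        fh.readline()
        for line in fh:
            sp, seq = line.rstrip("\n").split("\t")
            haplotypes[sp] = seq
    errors: list[InjectedError] = []
    with open(prefix.with_suffix(".errors.tsv")) as fh:
        fh.readline()
        for line in fh:
            rid, pos, fb, tb = line.rstrip("\n").split("\t")
            errors.append(InjectedError(rid, int(pos), fb, tb))
    pg: dict[str, list[int]] = {}
    indels: dict[str, list[int]] = {}
    with open(prefix.with_suffix(".pseudogenes.tsv")) as fh:
        fh.readline()
        for line in fh:
            rid, subs, ind = (line.rstrip("\n").split("\t") + ["", ""])[:3]
            pg[rid] = [int(x) for x in subs.split(",") if x]
            if ind:
                indels[rid] = [int(x) for x in ind.split(",")]
    return GroundTruth(
        base_modal=base_modal,
        species_haplotypes=haplotypes,
        injected_errors=errors,
        pseudogene_records=pg,
        pseudogene_indels=indels,
    )
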