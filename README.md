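# vlfqc

Frequency-matrix quality control for large multi-species DNA-barcode
alignments.

Reference barcode libraries (canonically the 648-bp / 216-codon 5' region of
mitochondrial COI) now hold thousands of sequences per taxon. Because COI is
under tight functional constraint, most alignment positions — especially
second codon positions — are conserved across essentially every species in a
class-level dataset. `vlfqc` exploits this: a residue carried by fewer than
0.1% of the sequences scored at an otherwise conserved column (a
**very-low-frequency variant, VLF**) is either a sequencing error, a rare
biological variant, or part of a co-amplified nuclear pseudogene (NUMT). The
package is for curators and users of barcode reference libraries who want a
direct, sequence-only estimate of database error and a screen for cryptic
pseudogenes that pass the usual stop-codon checks.

## Method

For every alignment column the fraction of sequences carrying each
nucleotide (or, after translation under the vertebrate mitochondrial code,
each amino acid) is recorded in a frequency matrix, excluding missing data
from the denominator. The most abundant (1st modal) and second most
abundant (2nd modal) residues define modal sequences; each record is scored
by its differences from the 1st modal sequence per codon-position class.
VLFs are sorted within species into **singletons** (one individual of a
species; spatially concentrated at the segment ends where Sanger read
quality decays — the signature of sequencing error) and **shared** variants
(two or more conspecific individuals with the same residue at the same
position — inherited variation, or a pseudogene when many cluster in one
record).

Because second codon positions are almost perfectly conserved, singleton
nucleotide VLFs at those sites bound the error rate from above:

    rate = n_singleton_codon2 / (n_records_multi × n_codon2_sites)

where `n_records_multi` counts only records of species with ≥2 records
(single-record species cannot be classified and are excluded from both
numerator and denominator). Records whose *shared amino-acid* VLF count
reaches 3 are flagged as cryptic-pseudogene candidates, with stop codons,
internal indels, and Kimura 2-parameter (K2P) distance to clean conspecifics
reported as corroborating evidence. Cohorts (e.g. deposition periods) are
compared by the prevalence of records bearing ≥1 singleton nVLF, with
Wilson 95% confidence intervals.

A ground-truthed simulator generates alignments with the same structure —
codon-class conservation hierarchy, species-shared haplotypes,
terminal-biased errors, engineered stop-free pseudogenes — so every stage
of the pipeline is testable offline.

## Worked example

Simulate a 300-species study with a deliberately high error rate
(5×10⁻⁴ errors/nt, 70% of errors in the two 100-nt terminal spans), then
estimate the error rate back from the alignment alone:

```
$ vlfqc simulate --seed 7 --n-species 300 --error-rate 5e-4 \
      --out demo.fasta --truth-prefix demo
wrote 1229 records (300 species) to demo.fasta

$ vlfqc error-rate demo.fasta --threshold 0.005
102 singleton codon-2 nVLFs / (1161 records x 216 sites) = 0.000407 errors/nt = 0.264 errors/barcode

$ vlfqc pseudo demo.fasta --out flags.tsv
0 candidate(s) among 0 record(s) with shared aaVLFs
```

The estimator recovers the injected rate (0.000407 vs 5×10⁻⁴; it is a
Poisson-noisy upper bound), and no pseudogene candidates appear because none
were injected. Note the detection threshold: at ~1,200 records the 0.1%
cut admits only single-copy residues, so desk-scale runs use the
scale-equivalent 0.5% cut (see `docs/methods.md`).

The library surface shows the conservation hierarchy directly:

```python
import vlfqc as v

aln = v.read_alignment("demo.fasta")
fm = v.build_matrix(aln)
modal = v.modal_sequence(fm)
diffs = [v.count_differences(r.sequence, modal) for r in aln]
summary = v.conservation_summary(fm, diffs)
for label, cc in summary.items():
    print(label, cc.n_sites, cc.percentages(), round(cc.mean_diffs, 1))
```

prints

```
codon1 216 (52, 72, 98) 5.4
codon2 216 (68, 85, 97) 0.4
codon3 216 (0, 0, 88) 71.1
```

i.e. per class: sites fully conserved, >99.9% conserved, and within the top
two residues >99.9% of the time, plus mean differences per record from the
modal sequence — second positions most constrained, third positions least,
exactly the structure the error estimator relies on. Singleton VLFs
concentrate at the segment ends (`terminal_enrichment` ≈ 2.6 for this run,
against 1.0 for a uniform spread).

`vlfqc run-all in.fasta --outdir out/` writes the full report bundle
(frequency matrices, observation tables, conservation and VLF summaries,
spatial profiles, error-rate report, pseudogene flags, cohort comparison)
as deterministic, provenance-headed TSVs.

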