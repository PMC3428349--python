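# Methods

## The model

`vlfqc` treats a multi-species alignment of a protein-coding barcode as a
column-wise categorical sample. For column *j*, let *n_j* be the number of
records with a canonical residue there (the *scored* count) and *c_j(r)* the
count of residue *r*. The frequency matrix stores the exact ratios
*c_j(r)/n_j*; the 1st/2nd modal residues are the two largest. Everything
else is derived from this object:

* **VLF detection.** Residue *r* at column *j* is a very-low-frequency
  variant iff *c_j(r)/n_j* < θ (default θ = 0.1%) and *r* is not the 1st
  modal residue. The comparison is made on the exact rational, never on a
  rounded percentage, so "<0.1%" and the complementary ">99.9%" conservation
  bucket partition columns exactly.
* **Species classification.** A VLF observation is *shared* iff ≥2 records
  of the same species carry the same residue at the same position (allele
  identity — two conspecifics with different rare residues are two
  singletons); *singleton* iff exactly one such record and the species has
  ≥2 records; *indeterminate* iff the species has a single record.
  Indeterminate observations are excluded from the singleton/shared census
  and from the error-rate numerator.
* **Error rate.** Assuming errors strike codon positions uniformly, the
  per-nucleotide upper bound is
  `n_singleton_codon2 / (n_records_multi × n_codon2_sites)`, with the
  denominator restricted to records of species with ≥2 records. It is an
  upper bound because some singletons may be genuine rare variants; no
  back-mutation correction is applied (shared sites are ~2% of sequences,
  a negligible contribution).
* **Pseudogene flagging.** The verdict is based solely on the per-record
  count of *shared amino-acid* VLFs reaching the flag threshold (default 3).
  Stop codons, internal indels (frame-preserving and frame-disrupting
  reported separately — a genuine 3-bp deletion is diagnostic even though it
  preserves frame), and minimum K2P distance to non-flagged conspecifics
  (advisory "deep divergence" at ≥2%) are corroborating evidence, not gates:
  the interesting pseudogenes are the ones a stop-codon screen passes.
* **K2P.** `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)` with transition/transversion
  proportions P, Q over pairwise-complete canonical sites (pairwise
  deletion). Out-of-domain logs raise a saturation error carrying the site
  counts.
* **Cohorts.** Per-cohort prevalence of records bearing ≥1 singleton nVLF,
  with Wilson 95% intervals (well-behaved at small counts; the interval
  always contains the point estimate). Exclusion predicates (records
  without conspecifics, known pseudogenes, ...) are the caller's.

## Conventions and numerical choices

* **Missing data.** N and all IUPAC ambiguity codes are missing — excluded
  from column denominators, never fractionally counted (fractional counts
  would make the θ cut ill-defined). Terminal gap runs are missing
  (incomplete reads); internal gaps are tracked separately and surfaced to
  the pseudogene module. Codons containing any non-canonical base translate
  to `X`, which is the amino-acid missing marker; an observed stop `*` is a
  countable residue state.
* **Tie-break.** Equal column counts are ranked alphabetically and the
  column is flagged as tied, making modal sequences deterministic across
  platforms.
* **Coordinates.** 1-based inclusive in all reports; 0-based half-open
  internally. Codon class of nucleotide position *p* is
  `((p−1−frame_offset) mod 3) + 1`.
* **Rounding.** Report means (VLFs per bearing sequence, conservation
  percentages) round half-up, so 274/202 = 1.36 reports as 1.4.
* **Degenerate inputs.** Empty alignments, unequal lengths, duplicate ids,
  foreign characters (named with record and position), frame violations,
  zero error-rate denominators, and K2P pairs without a complete site all
  raise typed errors; all-missing columns are kept but marked unscorable
  and excluded from class sizes rather than counted as conserved.
* **"Variance ratio".** The per-class variability ratio is defined as the
  ratio of per-class mean differences vs the 1st modal sequence, normalised
  to codon 2. (From class means 5.6 / 0.5 / 72 this gives 11.2 : 1 : 144.)
* **Threshold scale-dependence.** θ = 0.1% is calibrated to surveys of
  ~10⁴ records, where it admits variants carried by up to ~11 copies. In a
  ~1,200-record study it admits only single copies: shared variants cannot
  qualify at all, and colliding errors (two records, same column, same
  residue) escape detection, biasing the error estimate low. Desk-scale
  analyses in this package therefore use the scale-equivalent 0.5% cut
  (≤5 copies of ~1,200). Choose θ so that θ·n is roughly 5–10 for your n.

## The simulator

The generator emulates the conditions of a class-level barcode survey at
desk scale. Defaults: 300 species; records per species geometric with floor
1, mean 4 (large surveys average ~4 records/species with a long tail, and a
~20–25% share of single-record species arises naturally); 648 nt in frame;
per-site haplotype diversity by codon class 0.026 / 0.002 / 0.33 (observed
class means of differences vs modal divided by 216 sites); error rate
8×10⁻⁵ errors/nt with 70% of errors placed in the two 100-nt terminal spans
(Sanger read-quality decay); no pseudogenes unless requested.

Species variation uses two channels, both respecting the codon-class
hierarchy:

1. **Common binary polymorphism** — a column carries one alternative allele
   at a species-level minor frequency well above θ. This reproduces the
   "mostly binary, never VLF" character of real interspecific variation;
   generating species mutations independently instead would give every
   ordinary species several rare-column amino-acid variants and flag it as
   a pseudogene.
2. **Rare species-private variants** (per-species Poisson rates
   0.02/0.01/0.02 by class, sized from the observed census of ~60 in 2,133
   species with one or two shared aaVLFs) — the biological source of shared
   VLFs.

Structural guarantees, enforced at generation time: every haplotype is
stop-free under the vertebrate mitochondrial code (substitutions creating a
stop are reverted toward the ancestral codon), and the ancestral base stays
*strictly* modal at every column after record-weighting — which is what
makes "modal sequence of an error-free run equals the generator consensus"
an exact oracle rather than a high-probability one. Pseudogene carriers get
an engineered haplotype: amino-acid-changing substitutions at second codon
positions (stop-free by construction), plus extra divergence toward the K2P
target spread 70% at third positions (the divergence target is approximate;
multiple hits are not corrected), plus an optional gap run modelling a
deletion in aligned coordinates.

Not modelled: phylogenetic correlation between species (haplotypes are
independent draws from the ancestor — adequate for column-frequency
statistics, wrong for tree-based analyses), ambiguity codes and partial
reads, indels outside the pseudogene option, and insertions (which would
re-shape the alignment itself). Passing tests therefore demonstrate the
pipeline's arithmetic and recovery behaviour under the stated generative
conditions, not robustness to misalignment or base-composition artefacts of
real chromatograms.

## Problem sizes in the test suite

The suite runs simulations of 40–600 species (~120–2,400 records), sizes at
which every stage completes in seconds while keeping Poisson counts large
enough for the stochastic recovery checks (all seeded). The estimator
recovery check uses 300 species at 5×10⁻⁴ errors/nt and a 3-Poisson-SD
band; pseudogene recovery uses 600 species (~2,400 records) so that
2-carrier variants sit below the default 0.1% cut; the cohort comparison
uses two 250-species cohorts (~2,000 records) with per-record error means
0.3 vs 0.05.

## Known limitations

* The error estimator needs near-total second-position conservation;
  datasets with diverse second positions (distant taxa mixed, saturated
  groups) break the premise.
* The θ cut and the flag threshold are count-scale-dependent (see above);
  results on small alignments are sensitive to θ.
* Shared VLFs conflate inherited variation, shared errors, and pseudogenes;
  only the multi-VLF clustering (flagging) separates the last group, and
  trace-file or conspecific-sequence review remains the confirmatory step.
* Alignment itself is upstream: `vlfqc` trusts the input columns and only
  trims.
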