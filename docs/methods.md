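# Methods

This note records the models, rules and numerical choices behind
`baiscan`, including the places where the design was genuinely open and
what the synthetic data does and does not emulate.

## Reference database

The database is the union of a trusted seed set of bai amino-acid
sequences (family labels taken as given, no re-validation) and ORFs
recruited from candidate genomes. An ORF matches family *g* when some seed
of *g* aligns at identity ≥ 0.70 with alignment length ≥ 0.70 × the 90th
quantile of alignment lengths recorded for *g*. Choices fixed here:

* **Quantile rule** — linear interpolation between order statistics (the
  numpy default), so lengths 1..10 give 9.1. Fixed for reproducibility.
* **Quantile population** — the 90th quantile is taken over all
  seed-vs-ORF alignments of that family that pass the identity cutoff,
  collected in a first pass; the length rule is applied in a second pass so
  the result cannot depend on input order.
* **Dereplication** — an ORF matching several families keeps its
  best-identity family (ties to the lexicographically first family name);
  a genome contributes at most one ORF per family (best identity, ties to
  the smaller ORF id). A genome enters the database only with matches in
  ≥ 4 of the 8 families.

## Alignment

All pairwise protein alignment goes through one pluggable contract that
reports the best local alignment's score, matching residues and alignment
length. Identity is always matches / alignment length *including gap
columns*, the reporting convention of standard translated-search tools, so
thresholds are comparable to published practice. The built-in backend is
biotite's affine-gap local Smith-Waterman with BLOSUM62, gap open 11 /
extend 1 (a gap of length L costs 11 + (L−1)·1). `X` never counts as a
match. The test suite holds this backend against an independently written
full Smith-Waterman dynamic program (numba): scores must agree exactly;
identity and match count must agree exactly on substitution-only pairs and
within 0.02–0.03 identity on unrelated pairs, where co-optimal tracebacks
can legitimately differ.

## Read QC

Order is fixed: trailing trim (drop 3′ bases with quality < 20), then
sliding-window trim, then the ≥ 75 nt length filter. The sliding-window
rule clips at the *start* of the first 4-base window (5′→3′) whose mean
quality is below 20; reads shorter than the window are judged as a single
window of their full length. This is a deliberate simplification of the
classic trimmer's behaviour (which re-scans inside the failing window);
the clip-at-window-start rule is unambiguous and is what the tests pin
down. Trimming never edits bases, only truncates the 3′ end. Phred+33 is
assumed; scores above 60 are taken as evidence of Phred+64 input and
rejected. A vectorized batch implementation is cross-checked
property-by-property against the per-read reference implementation. Host
read removal is exposed as a pluggable predicate whose default flags
nothing, since synthetic communities contain no host DNA.

## Translated profiling

Reads are translated in all six frames; stop codons split a frame into
segments, each handled independently; segments shorter than 25 aa cannot
satisfy the length threshold and are skipped. A read keeps its single best
hit — highest alignment score, ties to the lexicographically smallest
reference sequence id — subject to identity ≥ 0.90 and alignment length
≥ 25 aa. An exact amino-acid 5-mer prefilter shortlists reference
candidates before alignment; a segment sharing no 5-mer with a reference
cannot reach 90% identity over 25 residues, so the filter changes cost,
not results (asserted by a batch-vs-single-read equivalence test).

Per-gene abundance divides each family's read count by the QC-passed read
count. Operon abundance is the geometric mean across the eight families
with zeros replaced by the 10⁻⁹ pseudocount — applied at the fraction
level, not the count level. The same rule produces per-cluster abundances
from each read's best-hit cluster, and a cluster is detected in a sample
when ≥ 4 of its families recruited ≥ 1 read.

## Operon clustering

Per genome pair, same-family sequences are aligned and pooled: averaged
identity = Σ matching residues / Σ alignment lengths over shared families.
Open points resolved here:

* **Coverage denominator** — "total bai gene sequence length" is taken as
  the mean of the two genomes' summed bai lengths, a symmetric choice;
  pairs with pooled alignment length < 80% of it are excluded.
* **Clustering rule** — single linkage: connected components of the graph
  whose edges are non-excluded pairs at ≥ 90% averaged identity. It needs
  no extra parameters and is independent of input order; note that other
  linkage rules could split chained clusters differently. Cluster ids are
  canonical (ordered by smallest member genome id), so membership is
  invariant under input permutation.

## Statistics

* High-SBA ⇔ DCA/CA > 1; an exact tie is labelled low-SBA ("high" means
  strictly more DCA), a measure-zero case in real data.
* χ² uses expected counts from the margins, dof = (r−1)(c−1); continuity
  correction only for 2×2 tables. Zero margins are an error.
* Mann-Whitney U is two-sided with midrank tie handling and normal
  approximation; AUC = U/(n₁·n₂) with U counting pairs where the second
  group's value exceeds the first's (ties count ½).
* Theil-Sen: slope = median of all pairwise slopes (equal-x pairs
  skipped); intercept = median of y − slope·x (the "joint" convention).
* Cluster "mean abundance when detected" is the mean of log₁₀ abundances
  over detected samples, reported as 10^mean — a mean of logs, not a log
  of means, consistent with the geometric-mean abundance scale.
* FMT fold change = geometric mean of post-FMT operon abundances /
  geometric mean of pre-FMT abundances; the pseudocount floor keeps it
  finite when no bai genes were detectable before transplant.
* Raw p-values throughout; no multiple-testing correction.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth at every level. Reference operons
descend from a per-family root: cluster ancestors are mutated at half the
between-cluster divergence, genomes at the within-cluster divergence, so
pairwise identity is ≈ 1 − 2·w within clusters and below 1 − b across
them. Genes are reverse-translated with uniform seeded codon choice; reads
are in-frame fragments at uniform offsets on either strand; background
reads are i.i.d. uniform nucleotides, which makes spurious ≥ 90%/25 aa
protein hits vanishingly rare (none observed in any test run). Sequencing
error is off by default so threshold behaviour can be probed with explicit
substitutions. Quality strings are constant Q37, with a configurable
fraction of reads set to Q10 to exercise the trimmer.

The cohort model assigns each sample a community state: *healthy-pair*
(clusters 1 and 2 present with correlated log₁₀ per-gene abundances around
10⁻³), *alt* (only the last cluster present), or *deficient* (no bai
carriers). State probabilities default to diagnosis-coupled rates with
SBA-deficiency at 30% (CD), 16% (UC) and 4% (non-IBD), mirroring the
reported frequency of the deficient state in IBD case-control cohorts.
log₁₀(DCA:CA) is drawn at ±1 (sign set by true operon abundance vs the
10⁻⁷ threshold) with configurable noise; CA is drawn around 10⁶ arbitrary
ion-abundance units.

Deliberately not modelled: realistic taxonomic composition, codon bias,
insert-size and per-base error profiles, host reads, and paired-end
structure. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's rules, not robustness to sequencing-error
modes absent from the simulation.

## Problem sizes and calibration of the study conditions

* Abundance recovery uses per-gene abundance 10⁻³ at 10⁵ reads — about
  100 expected reads per family — over 20 seeded replicates, requiring all
  eight families within 3 Poisson standard deviations in ≥ 95% of
  replicates.
* The discrimination cohort is n = 100 samples at 10⁴ reads each, with a
  balanced composition (≈ half above and half below the abundance
  threshold, the 50/50 design of the discrimination study). With no
  metabolome noise the AUC must be exactly 1.0; the noisy variant uses
  log-ratio noise sd 0.7, which flips ≈ 8% of labels (the draws landing
  near the ratio boundary) and is expected to keep the AUC near 0.92
  across replicate noise draws.
* The diagnosis-coupled cohort (n = 60) exercises the χ² design (3 × 2,
  dof 2), cluster prevalence and the correlation sign structure: clusters
  1 and 2 positively correlated, cluster 3 anti-correlated with both.
* The FMT cohort uses 10 subjects, half engrafting from the 10⁻⁹ floor to
  10⁻⁶ per family (fold change 10³), with engraftment-response coupling 1
  and a 1,000-permutation label control centring the AUC on 0.5.

All randomness flows from a single integer seed through named child
generators, so identical configurations give byte-identical FASTA/FASTQ/
TSV/JSON outputs (asserted by the determinism tests).

## Known limitations

* The six-frame search aligns each stop-free segment independently;
  frameshift-spanning hits are not modelled.
* Single-linkage clustering can chain near-threshold pairs; the averaged
  identity is pooled over shared families only, so genomes sharing few
  families rely on the 80% coverage rule for exclusion.
* Paired-end mates are treated as independent reads; the abundance
  denominator counts every QC-passed read.
* The naive uniform-background model understates database-level false
  positives that real, protein-coding non-bai sequence could produce;
  discriminating bai genes from distant homologues is outside the
  generator's scope.
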