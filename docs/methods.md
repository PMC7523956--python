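# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open. GFF3 and RepeatMasker
`.out` use 1-based inclusive positions; conversion happens only in
`myriakit.io`, so no analysis code ever reasons about off-by-ones.
Hairpin-local coordinates always run 5′→3′ along the hairpin RNA
regardless of genomic strand: on the minus strand a mature arm at genomic
`[ms, me)` inside hairpin `[hs, he)` maps to local `(he − me, he − ms)`.

## Arm-usage analysis

### Quantification

Reads are preprocessed in three steps, in order: (1) if a 3′ adapter is
configured, the read is cut at the leftmost exact occurrence of the
adapter's first 8 nt; (2) 3′ bases are trimmed until the terminal base has
Phred ≥ 20; (3) the read is kept if every remaining base is ≥ Q20 and its
length is within 18–27 nt. The quality rule is deliberately both a trim
and a whole-read filter: "bases below Q20 are removed" is ambiguous
between the two readings, so both are applied, which is idempotent and
strictly conservative.

Placement is ungapped matching of each read against every hairpin at
every offset — mature miRNAs are short enough that indels are vanishingly
rare, and ungapped matching makes the exhaustive-oracle test exact. The
default `max_mismatch` is 0 (configurable up to 2); among admissible
placements only minimal-mismatch ones survive. A read whose best
placements hit two different families is discarded outright rather than
fractionally shared: the downstream analysis excludes multi-copy cases
anyway, so fractional counting would add complexity that nothing
consumes. A read hitting several identical-sequence loci of one family is
counted once (toward the lexicographically first locus) and flags the
family as multi-copy; families whose annotation already links
identical-mature copies are flagged regardless of read evidence, since
the exclusion is a property of the genome, not of one library.

A placement is assigned to the arm that contains a strict majority
(> 50%) of the read's bases; exact ties (11 nt in each arm of a 22 nt
read) are unassigned. The strict-majority rule is symmetric between arms
and auditable base by base.

### ω, dominance, consensus, switching

ω = count_5p / (count_5p + count_3p), undefined when both are zero. A
(family, sample) record is included iff max(count_5p, count_3p) > 50;
included records are 5p-dominant iff ω > 0.7 and 3p-dominant iff ω < 0.3.
All three comparisons are strict: values landing exactly on a threshold
do not produce a call.

The species-level consensus takes included samples as its denominator: a
sample excluded by the count filter carries no dominance information, so
counting it against consensus would conflate expression level with arm
choice (this is a documented choice; the alternative — all samples in the
denominator — is one flag away in `species_consensus`). A consensus
requires one dominance category in strictly more than 70% of included
samples; a single included sample can therefore set a consensus, and
`n_included_samples` is reported so users can filter by support. An arm
switch between two species is exactly {5p, 3p} — unresolved, no-data and
multi-copy categories never participate.

The model wrapper (`ArmUsageModel` / `ArmUsageResults`) vectorises these
rules over a count table and attaches the binomial standard error
√(ω(1−ω)/n) to each estimate; it introduces no rule of its own.

### Genomic miRNA clusters

Single-linkage chaining per scaffold: consecutive loci join a cluster
when the end-to-start gap is ≤ `max_gap` (default 10 kb — the common
operational definition of a miRNA cluster; configurable), and clusters
need ≥ 2 members. Chaining is monotone in `max_gap`.

### Reporter normalisation

For dual-luciferase sensor assays, each construct's Renilla/firefly ratio
is averaged over replicates and divided by the matched sensor-only
control's ratio; the relative 5p-to-3p activity is the quotient of the
two normalised values. A missing control is an error naming the
construct. A plain Welch t statistic is available for convenience; no
inference beyond it is attempted.

## Synthetic data

The generator's job is recoverability under known truth, not biological
realism.

* **Hairpins**: random arms of 20–24 nt joined by an 8–15 nt loop; the 3p
  arm is the reverse complement of the 5p arm with three substitutions
  (an imperfect stem keeps the arms distinguishable). A chosen fraction
  of families is emitted as two identical loci to exercise the
  multi-copy exclusion.
* **Reads**: per locus, Poisson(depth_mean) reads; each is drawn from the
  5p arm with probability equal to the family's true ω, or from the loop
  with probability 2% (modelling degradation fragments). Read ends are
  jittered N(0, 1 nt) and rounded, lengths clamped to 18–27 nt,
  substitution errors applied i.i.d. at 1% per base. Qualities are
  two-level — Q40 everywhere, Q15 at error positions — which is enough to
  exercise the Q20 filter without modelling real quality profiles.
  Defaults (depth 2,000; error 0.01; loop 0.02; jitter 1 nt) are the
  study conditions the recovery checks run at.
* **Truth**: non-switch families share one ω across species, drawn 40%
  strongly 5p (U(0.85, 0.98)), 40% strongly 3p (U(0.02, 0.15)), 20%
  balanced (U(0.35, 0.65)); planted switches pair a strong-5p with a
  strong-3p value (separation ≥ 0.7), comfortably beyond the 0.3/0.7
  cut-offs at design depth.
* **Seeding**: one integer seed; each (sample, miRNA) pair gets its own
  named child stream (seed plus CRC32 of the names fed to numpy's
  `SeedSequence`), so adding a sample or miRNA never perturbs the reads
  of existing ones.
* **Genome fixtures**: scaffolds are assembled left to right from genes
  (fixed exon/intron sizes), repeats placed either 1 kb from a gene
  (genic) or > 2 kb from every gene (intergenic), telomeric arrays at
  chosen ends, and random background. Features never overlap, so the
  truth ledger is exact by construction and the pipeline must match it
  exactly, not approximately. Divergence values come from a
  young/old Gaussian mixture (means 3% and 25%), rounded to 0.1% as the
  RepeatMasker table prints them, so the file round trip is lossless.

What passing recovery tests on this generator shows: the counting,
filtering, thresholding and consensus machinery implements its rules
correctly at realistic depths. What it does not show: robustness to
adapter chemistry, ligation bias, isomiR distributions, quality-score
structure, or repeat nesting in real genomes — none of which the
generator attempts to emulate.

## Genome composition

* Per-class repeat bp merges overlapping intervals within the class; the
  total merges across classes. Raw (unmerged) sums are reported next to
  the unions because upstream annotations may legitimately overlap and
  published totals rarely state which convention they used.
* Genic vs intergenic: a repeat is genic iff its gap to some gene is at
  most 2 kb — implemented as overlap-or-touch against gene intervals
  expanded by the window (clamped at zero). The boundary case (gap of
  exactly 2,000 bp) counts as genic. Whole features are assigned to one
  category, so genic + intergenic equals the per-class total exactly for
  non-overlapping annotations.
* The size decomposition (genome, repeat, non-repeat, exon, intron) is
  exact integer bp; Mb display values round half away from zero, and
  integer percentages match report conventions while full precision is
  retained in machine columns. When two genomes are compared after repeat
  exclusion, both directional percentage differences are available
  (`nonrepeat_ratio_pcts`) since "X% greater" claims are
  direction-dependent.
* Kimura landscapes bin each repeat copy's (CpG-adjusted) divergence —
  accepted as an input column, not re-derived from alignments — into 1%
  bins up to 50%, with older copies pooled into an overflow bin; bin mass
  is 100·aligned_bp/genome_bp, so total mass equals the repeat
  percentage.
* `kimura_distance` implements d = −½ ln((1 − 2P − Q)√(1 − 2Q)) and
  raises a domain error at 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 rather than
  saturating silently.
* Telomere scanning counts the longest tandem run of the motif (default
  TTAGG, the canonical arthropod telomeric repeat; configurable) or its
  reverse complement within 10 kb of each scaffold end; presence needs
  ≥ 25 tandem copies. For sequences shorter than the window both ends see
  the whole sequence.

## Problem sizes and numerical choices

The recovery study runs 200 miRNA families × 2 species × 3 stages at
depth 2,000 (~2.4 M reads), streamed one library at a time so memory
stays at a single library; it completes in well under a minute on one
core. Exact-match placement uses a substring index over all hairpin
windows of the observed read lengths; mismatch-tolerant placement falls
back to full enumeration and is intended for small instances and oracle
tests. Floating-point comparisons in tests use explicit tolerances only
where a quantity is genuinely real-valued (ω errors, landscape mass);
every bp ledger comparison is exact integer equality.

## Known limitations

* Reads are matched directly to hairpins rather than genome-wide; for a
  hairpin set whose arms are unique in the genome this is equivalent, but
  reads from elsewhere in a real genome that happen to match a hairpin
  would be miscounted. The multi-family discard rule limits, but does not
  eliminate, this.
* Cross-species family matching is by family name, not inferred
  orthology.
* The generator's arm-usage distribution is chosen for test power; real
  arm-usage distributions are broader and the undetermined band is likely
  to be more populated in real data.
* CpG adjustment of divergence values is trusted as annotated upstream.
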