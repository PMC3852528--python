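# Methods

`repeatscope` re-creates, as a tested library, the workflow used in
low-coverage genome survey studies to characterize a plant genome's
repetitive fraction: split-then-assemble repeat consensus building,
read-depth redundancy classification, similarity-based repeat annotation
and family clustering, read-count genome composition, and LTR/inter-LTR
coverage ratios for solo-LTR inference. This note records the models,
parameter choices and numerical conventions behind each stage, what the
synthetic genomes do and do not emulate, and the known limitations.

## The survey model

At sub-1x coverage almost no specific genomic locus is sampled deeply
enough to assemble, but a repeat family with c copies is effectively
sampled at c times the nominal coverage, so assembled contigs are
*consensus sequences of repeat families* rather than loci. Splitting a
read set into many very-low-coverage subpackages before assembly pushes
this further: in a subpackage at coverage t, only families with roughly
c >= 3/t reach assemblable depth, so subpackage contigs are strongly
enriched for high-copy repeats. The pipeline assembles each read package
both ways (split and unsplit), merges everything into one whole-genome
assembled sequence set ("WGSAS" in the survey literature), and measures
each contig's redundancy by mapping a deeper read set back to it.

The redundancy statistic is **average coverage**: the sum of the aligned
bases of all reads placed on a reference divided by the reference
length. Multi-reads are placed at one best-scoring locus chosen
uniformly at random, so a single contig's average coverage is an
indication, and the sum over a family or class an unbiased estimate, of
genomic abundance.

## Synthetic genomes

The generator plants a declared census into an i.i.d.-uniform random
background: LTR retrotransposon families (LTR + internal + identical
LTR, plus optional solo-LTR copies), DNA transposons (MITEs get a 15-nt
terminal inverted repeat), tandem arrays, rDNA-like elements and
single-copy genes. Copies diverge from the canonical element by
independent per-base substitutions; elements are planted without
overlap, positions uniform over the free space. An organellar pool is
generated separately and sampled into the read stream at a configurable
fraction — mirroring how surveys treat organellar reads as contaminants
counted apart — but never planted in the nuclear sequence.

Reads are single-end with uniform starts, equiprobable strands,
per-base substitutions and single-base indels. Read count is set so
total read bases hit the requested coverage within one read length.

Deliberately not emulated: nested or truncated element insertions,
GC/composition bias, quality-score structure, PCR duplicates,
paired-end inserts. Passing recovery tests therefore demonstrates the
pipeline's arithmetic and its behavior under sampling noise, divergence
and sequencing error — not robustness to the full structural complexity
of real plant genomes.

### Default study conditions

The standard simulated study (`default_simulation`) uses a 1 Mb genome
whose planted fractions echo a repeat-dominated plant genome: two Gypsy
families (23.8% of the genome, one with 50 full copies), two Copia
families (14.3%, with solo-LTR to full-element ratios of 0, 1, 0.4 and
3 across the four LTR families), a CACTA family (7.5%), a MITE family
(100 copies, 4%), an rDNA-like element (7.2%), one 180-nt-unit tandem
array (5.4%), 20 single-copy genes and ~34% unique background; 5% of
reads are organellar. Family divergence is 1.5% (recently amplified
families — the regime in which repeat-consensus assembly is
meaningful), read error 0.5% substitutions / 0.1% indels, read length
101 nt. Assembly uses a 1x read set; redundancy mapping uses a 4x set,
matching the survey design of a shallow assembly set and a deeper
mapping set. Copy numbers scale with genome length so the class
proportions are scale-invariant; the subpackage coverage target scales
inversely (0.15x at 1 Mb) to hold per-family subpackage depth fixed.

The 1 Mb scale keeps a full pipeline run under a minute on one CPU
while leaving every class above the sampling noise floor; all recovery
figures quoted in the README come from this configuration.

## Assembly engine

The two assemblers used in the original surveys are closed-source or
external; a single greedy overlap-layout-consensus engine stands in for
both passes, parameterized to honor the printed thresholds (minimum
contig length 300 nt; merge identity 90%; read-pass identity 95%;
minimum overlap 40 nt). Candidate pairs come from shared canonical
16-mers (hash-subsampled 1-in-4 on inputs above 500 sequences, buckets
capped at 32 entries, 16 partners per sequence); overlaps are verified
by banded alignment (edlib) at the best-supported diagonal and scored
as overlap length minus edit distance. Greedy merging processes
overlaps best-first: dovetails chain sequences into layout paths (each
sequence end used once, cycles refused), containments absorb a sequence
into its host. Chaining is iterated to convergence (up to 4 rounds for
reads, 5 for contig merging): each round re-overlaps the previous
round's consensus fragments, so paths interrupted by local port
conflicts still coalesce. Consensus is per-column depth-weighted
majority vote, ties to the alphabetically first base; all ordering ties
break lexicographically by sequence id, making output deterministic for
a given input order.

Paired-end distance parameters from the original tooling are accepted
in configuration for fidelity but inert: the simulator emits single-end
reads only.

## Mapping engine

Placements come from exact 15-mer seeding on both strands (read k-mers
sampled at stride 3), diagonal voting, and edlib verification in a
padded window. The verified alignment is trimmed to its
maximum-scoring contiguous segment (Kadane over per-column
contributions: match +1, mismatch -2, insertion -3, deletion -3 by
default), which makes the alignment semi-global on the read — read ends
may be soft-clipped, so the `length_fraction` threshold (default 0.5)
is meaningful. A placement is valid if the aligned read fraction and
identity (default 0.8) pass; the best-scoring valid placement wins and
exact ties are resolved uniformly at random from a seeded stream. The
default costs follow common short-read-mapper conventions; because the
original survey's winning parameter set is not printed, the calibration
operation (`calibrate_mapping_params`) reproduces the selection
procedure — maximize the correlation between known redundancy and
average coverage over a reference panel — rather than any specific
outcome. Correlation is Pearson by default (the published calibration
compares a linear relationship) with a Spearman switch.

## Annotation and family statistics

Similarity search is ungapped seed-and-extend (word size 11, both
strands, X-drop 40) under a +4/-5 match/mismatch scheme. E-values use
the ungapped Karlin-Altschul formula `E = K m n exp(-lambda S)`;
`lambda` solves the transcendental normalization equation under uniform
base frequencies and `K` is computed from the classical lattice
convolution series (60 terms). For the +1/-2 and +1/-3 schemes the
implementation reproduces the well-known (1.33, 0.621) and
(1.37, 0.711) constants. Gapped statistics are out of scope; since
planted copies diverge by substitutions only, ungapped extension is the
right model here.

Annotation keeps, per contig, the hit with the longest match among
those at E <= 1e-10 (ties: smaller E-value, then lexicographic hit id);
unannotated contigs are screened for perfect SSRs (unit 1-6 nt, arrays
>= 24 nt) and low-entropy windows (< 1 bit over 64 nt, flagged when
>= 50% of the contig). Families are connected components over directed
best-hit edges at E <= 1e-50 — each contig points at its single most
similar other contig; components of size >= 2 are families, the rest
singletons. Self-hits are excluded and similarity ties break
lexicographically; the published description does not fix either
convention, so results can differ from the original at exact-tie
boundaries. Best-hit components implement single-linkage ("each
sequence sharing similarity is attributed to the same family"), not
mutual-best pairing.

## Redundancy threshold and composition

The repeated/low-copy threshold is a multiplier (default 5) times the
mean average coverage of known single-copy genes mapped alongside the
contigs; the comparison is strict (`> threshold`), so a contig exactly
at the cutoff is low-copy ("higher than five-fold"). Composition
attributes each placed read to the class of its best-match contig;
reads on low-copy contigs count as unique-or-low-redundant. Accounting
identities (class counts sum to matched; matched + unmatched = total
nuclear; matched percentages sum to 100.00 +/- 0.05 after rounding)
are enforced by the table constructor, not merely reported.
Percentages are exact ratios rounded half-up to 2 decimals only at
display.

## LTR / inter-LTR ratios

The two LTRs of an element are copies of one sequence, and coverage is
computed as if the LTR were a single reference: aligned bases falling
in either LTR interval are pooled and divided by the length of one
LTR. Under that convention a family of F intact elements and S
solo-LTRs has expected ratio (2F + S)/F = 2 + S/F, the closed form the
simulator's `expected_solo_ltr_ratio` returns; ratios strictly above 2
flag solo-LTR presence. Group and overall means are taken over
unrounded ratios (averaging the rounded ratios gives visibly different
group means on the published 19-element table); records with zero
internal coverage get an infinite-ratio sentinel and are excluded from
means. Ratios below 2 — produced in real genomes by families sharing
an internal region — are reported as-is, never "corrected".

Observed ratios run slightly below the closed form at high S/F when
the LTR is short: reads overlapping a 200-nt solo-LTR by less than the
length-fraction threshold are dropped entirely, so solo copies lose
proportionally more edge coverage than full elements. In the standard
study the family with S/F = 3 and a 200-nt LTR lands ~0.7 below its
expectation of 5 while the other three families sit within 0.3; the
ranking across families is preserved.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; human-readable reports
state their conventions in `#` header lines. Rounding is half-up
(`round_half_up`) at display only. Empty inputs return empty results
wherever the operation is total (assembly of no reads, statistics of no
contigs); undefined quantities raise (`class_ratio` with zero
denominator, solo-LTR ratio of a family with no intact copies,
correlation under zero variance — degenerate grid points are recorded
as missing and never selected). Every stage seed derives from one
global seed; reruns are byte-identical.

## Known limitations

* The assembler is a desk-scale greedy OLC; it honors the published
  thresholds but is not a re-implementation of any specific commercial
  assembler, and no chimera detection exists beyond the identity
  threshold.
* Family clustering operates on consensus contigs; fragments of one
  element that share no sequence correctly fail to cluster, so family
  counts under-represent fragmented families.
* Composition estimates for classes the assembly does not cover
  (unique background, single-copy genes at 1x) are structurally
  underestimated — exactly as in the original survey design, where
  unmatched reads are reported as their own category.
* E-value statistics are ungapped; indel-rich divergence would need
  gapped statistics and is out of scope.
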