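# Methods

## Model and assumptions

The method assumes a diploid genome in which a useful fraction of autosomal
CpG sites is methylated allele-specifically, and that a basecaller has
written per-read 5mC probabilities into `MM`/`ML` tags. It further assumes
an upstream SNV phasing whose within-block assignments are trustworthy:
blocks are only re-oriented relative to each other, never re-phased
internally ("benefit of the doubt" to the SNV phaser). Sex chromosomes are
excluded by default because random X inactivation decouples methylation
from haplotype; an `--include-sex` override exists for clonal samples and
organisms with skewed inactivation.

Modification probabilities are decoded from the 256-bin `ML` integer `v`
by the bin-midpoint rule `(v + 0.5)/256`, which is monotone and maps into
the open interval (0, 1). Calls are projected from read to reference
coordinates through the CIGAR; calls without a reference anchor
(insertions, soft clips) are dropped, since ASM profiles are keyed by
reference CpG positions. Reverse-strand calls sit on the CpG's G and are
folded onto the forward-strand C (CpG methylation is symmetric); this
merge is toggleable. Only primary alignments with mapping quality >= 10
contribute; supplementary alignments duplicate methylation evidence and
are excluded unless requested.

## Statistical test

Per CpG site inside an extended block, the two haplotypes' score samples
are compared with a two-sided Wilcoxon rank-sum (Mann-Whitney) test. The
exact null distribution is used when both samples have at most 25
observations and the pooled sample is tie-free; otherwise the normal
approximation with midranks, tie correction and continuity correction.
After a BAM round trip the scores are quantised to the 1/256 grid, so the
approximate path is the workhorse on file-based runs, while in-memory
simulated scores exercise the exact path. No multiple-testing correction
is applied across sites — the method thresholds each site at a plain
`alpha = 0.05`, and the consequence (about 5% false ASM sites under the
null) is absorbed downstream by the vote-count and confidence filters;
`alpha` is a config knob.

A consequence of the exact test worth knowing: with fewer than four scores
on either side the achievable two-sided p-value floor is above 0.05
(3-vs-3 gives at best 0.1), so a site needs at least 4 scores per
haplotype to ever become ASM. This drives the coverage requirements of the
defaults below.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | per-site significance level for ASM |
| `min_scores_per_hap` | 2 | floor for running the rank-sum test |
| `min_cov_per_hap` | 3 | per-haplotype coverage for a site to cast votes |
| `min_votes` | 3 | votes required to assign a read |
| `max_iterations` | 10 | cap on assignment iterations per block |
| mode | accuracy | relationship filter preset |
| `min_reads` | coverage/(blocks/1000) | accuracy-mode minimum bridging reads (ceil, floor 1) |
| `min_confidence` | 0.5 | accuracy-mode vote-confidence threshold (strict >) |
| `min_mapq` | 10 | mapping-quality filter on input reads |

The accuracy-mode `min_reads` formula is meant for genome-scale block
counts (thousands of blocks); on a single simulated chromosome with 10
blocks it would demand hundreds of reads, so desk-scale runs pass an
explicit `--min-reads` (10 in the examples, the formula's value for a
~2000-block genome at 20-25x). Coverage, when not supplied, is estimated
as mean depth over evenly spaced 1 kb windows.

Numerical choices: vote ties (a score exactly midway between the two
medians) abstain; equal vote counts leave a read unassigned; equal
same/switch votes leave a gap UNKNOWN; a tie for the largest gap skips the
leftmost. Iteration is synchronous — all votes in an iteration are cast
against the profiles committed at the end of the previous one — which
makes results independent of read order, and assignments are never
revoked. Degenerate inputs: a chromosome with a single block has no gaps
and passes through; an empty profile map or a block with no ASM sites
yields zero assignments in one iteration.

## Synthetic data

The generator plants every latent variable the method estimates, then
emits standard files (BAM with `MM`/`ML`/`HP`/`PS`, phased VCF, truth
tables as TSV), so each stage can be checked against ground truth.

Defaults (one simulated chromosome): 10 blocks of 12 kb separated by
homozygous gaps of 4.5 kb (sd 0.7 kb, min 1 kb); heterozygous SNVs every
1 kb inside blocks; CpGs every 150 bp; 50% of CpGs allele-specific with
scores drawn from Beta(8,2) on the high haplotype and Beta(2,8) on the
low, shared sites from Beta(5,5); reads lognormal with mean 10 kb (sigma
0.3) at 25x; 80% of reads overlapping >= 2 block hets are pre-tagged with
the block's planted orientation (modelling WhatsHap haplotag, which tags
most het-overlapping reads); block orientations and same/switch gap
relationships are planted per gap. Gap length is set to roughly half a
read length so that, at default coverage, every gap is crossed by at least
ten reads assignable on both sides — the regime in which the accuracy
filter can operate; rarer under-covered gaps are correctly left UNKNOWN
rather than mis-called. A `scramble_fraction` re-draws a read's
methylation from a random haplotype while keeping its SNV alleles,
modelling tissue heterogeneity / X-inactivation-like noise.

What the generator does *not* emulate: sequence errors and alignment
ambiguity (reads align perfectly with a single match operation), basecaller
score miscalibration, CpG density variation and DMR structure, segmental
duplications, and real centromere geometry (the "largest gap" skip is
exercised structurally, not against an annotation). Passing tests
therefore demonstrate the correctness of the algorithmic machinery and its
statistical calibration under the stated signal model, not performance on
real nanopore data, where ASM density and signal separation are locus- and
sample-dependent.

## Design choices

- The test is two-sided; ASM direction is irrelevant to voting, which uses
  closeness to per-haplotype medians (medians resist the occasional
  scrambled or miscalled read; means are available as an option).
- Reads SNV-tagged to a *different* phase set are treated as candidates in
  the current block, and a read's SNV tag counts as its label on that
  block's side of a gap; this is what lets a single long read bridge two
  blocks.
- A read assigned by both blocks flanking a gap is emitted once, with the
  earlier block's assignment.
- Chains renumber `PS` to the first member's id; flipping reverses
  genotype order only (`a|b -> b|a`), never allele content.
- Flip errors are isolated single-variant mismatches (two adjacent
  orientation changes collapsed); every remaining orientation change is a
  switch; per-block hamming is `min(mismatches, n − mismatches)`; rates
  are normalised by assessable adjacent phased pairs, following the
  WhatsHap-compare convention.

## Problem sizes

Tests and the acceptance script run on single simulated chromosomes of
~170 kb (~350-400 reads), five single-block datasets of ~46 kb for
assignment statistics, 2000 simulated null sites for calibration, and
exhaustive enumerations (rank partitions up to 8+8, chain orientation up
to 6 blocks) as independent oracles. These sizes were chosen so the full
suite completes in a few minutes while every code path — including the
iterative unlock of late sites and the UNKNOWN/skip chain breaks — is
exercised.

## Known limitations

- Initial SNV phasing errors propagate; blocks are never re-phased
  internally.
- The accuracy-mode `min_reads` formula presumes genome-scale block
  counts and needs an explicit override on small inputs.
- No probabilistic (soft) assignment; a read is H1, H2 or unassigned.
- 5hmC and non-CpG contexts are out of scope; only `C+m` streams are
  decoded.
- Relationships are inferred between adjacent blocks only; long-range
  evidence (Hi-C, Strand-seq, pedigrees) is not integrated.
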