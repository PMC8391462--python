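# Methods

This note documents the models, algorithms and defaults behind `pprealu`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Promoter windows and coordinates

Everything internal is 0-based half-open (BED convention); RepeatMasker
`.out` rows (1-based inclusive, strand `C` for minus) are converted at
parse time. A promoter window is the `L` bp upstream of a TSS: `[t−L, t)`
for a + gene and `[t+1, t+1+L)` for a − gene, with the sequence
reverse-complemented so window coordinate 0 is always the position farthest
upstream. Windows are clipped at contig edges with a logged warning. The
two analysis scales are 4 kb (discovery) and 2 kb (the conserved-site scan);
both are plain parameters.

## Configuration grammar matching

The repeat architecture is expressed as an ordered list of repeat
class/family terms, by default `SINE/Alu, SINE/Alu, Low_complexity,
LINE/L1`. A match assigns window-overlapping annotated repeats (≥1 bp
overlap; elements may extend past the window edge) to the terms such that
element start positions strictly increase in window coordinates and the gap
from one element's end to the next element's start is at most `max_gap`.
Defaults that the source material leaves qualitative ("proximal") are
explicit here: `max_gap = 500` bp, orientation policy `any` (a
`same_strand` policy is available). Overlapping repeats (negative gaps) are
tolerated — RepeatMasker annotations nest and overlap in practice. All
valid assignments are reported; a gene *qualifies* in the genome-wide scan
if it has at least one grammar match and at least one motif hit inside an
Alu element of such a match. The matcher is exhaustively checked against a
brute-force enumeration of ordered subsequences on windows with ≤12
repeats.

## PPRE motif scan

The default motif is the exact heptamer `TGACCTC`; IUPAC degeneracy is
supported but not used by default, since degenerate DR1 variants would
change what "a PPRE" means downstream. Both strands are searched (the
reverse complement `GAGGTCA` is the strongly conserved orientation inside
the Alu), overlapping occurrences are all reported, and a sequence `N`
never matches any motif symbol — including motif `N` — so scanning never
calls hits across assembly gaps. Hit strand is reported relative to the
reference.

## Alu structure annotation

When a hit falls inside an annotated `SINE/Alu` feature, the genomic copy
is extracted (reverse-complemented for − features), globally aligned to its
subfamily consensus, and the hit start is mapped through the alignment to a
consensus offset. Structural landmarks on the consensus default to the
canonical dimeric Alu layout: left arm `[0, 132)`, A-box `[6, 32)`, B-box
`[72, 101)`, A-rich linker up to 158, right arm beyond; all are
configurable per subfamily. "Adjacent to a box" means the heptamer interval
lies within 10 bp of the box interval; the B-box wins ties because it is
the landmark the architecture is anchored to. At 10% copy divergence the
alignment mapping stays within ±5 bp of the true offset in the planted
simulations.

## Consensus building (redundancy collapse, star MSA, majority call)

The consensus stage deliberately replaces heavyweight external tools with
small deterministic algorithms whose behavior is exactly testable:

- **Redundancy collapse**: greedy clustering in input order at a global
  identity threshold (default 0.95, identity = matches / alignment length);
  the cluster representative is its first member. This implements
  deduplication semantics, not assembly.
- **Pairwise alignment**: Needleman–Wunsch with linear gaps, defaults
  +1/−1/−2 chosen for oracle simplicity; traceback ties prefer diagonal,
  then up, then left, making alignments deterministic. Scores are verified
  against exhaustive enumeration for short sequences.
- **Star MSA**: the center is the sequence with maximal summed pairwise
  identity (ties to the first); all others are aligned to it pairwise and
  gaps merged by once-a-gap-always-a-gap. This is an approximation to
  progressive MSA that is adequate at intra-subfamily Alu divergence
  (substitution-dominated, few indels) and is exactly reproducible.
- **Consensus**: columns with gap fraction > 0.5 are dropped; per retained
  column the majority base over {A,C,G,T} wins, ties break alphabetically
  (no IUPAC ambiguity emitted), and information content is 2 − H bits of
  the gap-excluded base frequencies. At depth 20 and 5% substitution the
  majority vote recovers the seed sequence exactly with overwhelming
  probability; the suite asserts exact recovery over 20 random seeds.

## Distances and neighbor joining

Distances are p-distances over mutually non-gap columns (the simplest
defensible model for the short divergence ranges involved); Kimura
2-parameter is available behind a flag. Neighbor joining is the standard
Saitou–Nei agglomeration: join the pair minimizing the Q-criterion (ties
to the lowest row/column index), branch lengths from the usual formulas
with negative estimates clamped to zero and counted, final three nodes
joined at one internal node. For additive matrices NJ provably recovers
the generating tree; the suite verifies exact topology-and-length recovery
on 50 random 4–8-taxon additive matrices and cross-checks topology against
an independent NJ implementation. No attempt is made to reproduce any
particular external program's tree, whose distance model and gap handling
are unreported; subfamily granularity follows the input library.

## Statistics

- **Correlation**: sample Pearson r per (cancer type, cohort);
  significance via t = r√(n−2)/√(1−r²) on n−2 df, two-sided; Fisher-z 95%
  intervals reported alongside. The weak-correlation flag marks
  −0.5 < r < 0.5. Cohorts with n < 3 are skipped with a warning. P-values
  are reported raw per type (a Benjamini–Hochberg column can be added by
  the caller; the headline tables are raw).
- **KS**: D is the supremum ECDF difference over pooled sample points; the
  p-value uses the asymptotic Kolmogorov distribution with effective
  n = n₁n₂/(n₁+n₂). The asymptotic p is mildly conservative for small-to-
  moderate samples; an exact-distribution option exists for n ≤ 25 per
  sample, and the calibration simulations use 500 observations per arm,
  where the asymptotic null rejection rate at 0.05 is 0.050 (measured at
  20 000 replicates).
- **Null model for variant scores**: the null enumerates *all* missense
  single-nucleotide changes of the CDS by brute force (3 alternatives ×
  every position, translating codons; stop gains/losses excluded), rather
  than a random subsample — the exhaustive set is the cleaner reference
  distribution.
- **Survival**: median split with ties to low (the published cutpoint is
  unstated; the median is the conventional default and the quantile is
  configurable); Kaplan–Meier product-limit curves; two-group log-rank with
  the hypergeometric variance, no continuity correction, times with a
  single subject at risk skipped. Cross-checked against lifelines.

## Synthetic data: what it emulates and what it does not

The generators are driven by `numpy.random.default_rng` (PCG64), so a
fixed configuration reproduces byte-identical outputs anywhere.

- **Genome**: i.i.d. uniform ACGT background, genes on alternating strands
  at fixed spacing, promoter window 2 kb. Planted configurations place two
  Alu copies, a (TA)ₙ low-complexity run (50 bp) and a 400 bp L1 fragment
  in grammar order with gaps uniform on [1, 500], redrawn until the span
  fits the window (so plants are recoverable at both 2 kb and 4 kb scan
  scales); the heptamer is written at consensus offset 62 of the first Alu
  — left arm, 3 bp upstream of the B-box — in forward orientation for even
  plants and reverse-complement for odd ones. Copies are mutated from
  their subfamily consensus at the configured substitution rate (default
  5%, the intra-subfamily regime; the heptamer region is exempt, since the
  question under test is architecture recovery, not motif decay). Lone
  decoy Alus are dropped into a third of unplanted promoters as negative
  controls.
- **Consensus library**: 4 synthetic ~300 bp "subfamily" consensi derived
  from a common ancestor at ~10% substitution (≥12% pairwise divergence),
  scrubbed of the heptamer on both strands so every motif occurrence in a
  simulated genome is a planted one. These are synthetic stand-ins — real
  subfamily consensus FASTA can be supplied instead and flows through the
  same code paths.
- **Expression**: per cohort, two-gene standard bivariate normal with the
  configured population correlation, exponentiated into an FPKM-like range.
  Correlations are therefore exact on the log scale and attenuated on the
  raw scale; recovery checks use the latent scale. Defaults
  (r_control = 0.9, r_tumor = 0.1, n = 60 control / 300 tumor) mirror the
  strong-control/weak-tumor contrast and the control-poor composition of
  public tumor cohorts.
- **Mutations**: observed sets draw `n_observed = 107` variants (the size
  of the PPARγ catalogue analysed in the source study), a `band_fraction`
  of them from the 60–80 score band. The enrichment strength is a free
  knob with no published value; the default 0.4 produces an unambiguous
  but not caricatured KS departure. Scores themselves are pseudo-random
  stand-ins — computing real evolutionary-action scores is out of scope,
  and the tables are consumed as input.
- **Survival**: 80 cases, 39% monosomy 3 (the published cohort
  composition); expression log-normal; exponential event times with hazard
  0.06/yr for the high-expression arm vs 0.18/yr otherwise (high expression
  protective, hazard ratio 3 — large enough that an 80-case cohort has
  decent log-rank power), censored at 12 years.

What passing these tests shows: the scanner, aligners, tree builder and
statistics are correct on inputs whose truth is known, including under
realistic substitution noise. What they do not show: performance on real
genomes — real promoters have non-uniform base composition, CpG islands,
nested/truncated repeats and indel-mutated Alu copies (indels are
deliberately excluded from copy simulation), and real annotation tracks
carry boundary error. The architecture of the pipeline (annotations as
inputs, alignment-based context mapping) is designed to degrade gracefully
there, but quantitative sensitivity claims transfer only qualitatively.

## Numerical and determinism notes

- All tie-breaks (alignment traceback, consensus base, NJ join order,
  collapse order, match enumeration order) are fixed and documented, so
  every pipeline output is byte-identical under a fixed seed.
- Negative NJ branch-length estimates are clamped to 0 and counted on the
  tree object.
- KS/log-rank/correlation p-values are clamped into (0, 1].
- Degenerate inputs fail loudly: zero-variance correlation, constant
  median split, empty subgroups, all-gap consensus columns, non-positive
  survival times, |r| ≥ 1 in the expression generator.

## Problem sizes used by the checks

The bundled verification runs use 50-gene genomes (10 plants), 200 random
windows for the matcher oracle, 100 × 10 kb sequences for the scanner
oracle, 50 additive matrices for NJ, 20 × 20 copies for consensus recovery,
and 2000 null replicates per calibration estimate (at 2000 the [0.035,
0.065] acceptance band sits ±3 binomial SD from the true ≈0.05 rejection
rate, so the check is tight without being noise-dominated). A full
acceptance run completes in a couple of minutes on one CPU.

## Known limitations

- Star MSA has no guide-tree refinement and linear (not affine) gap
  penalties; it is not a general-purpose aligner.
- The exact criterion behind the published list of 11 similarly-configured
  genes is unstated upstream; the qualification rule here (grammar match +
  PPRE inside a matched Alu) is explicit and configurable, and the count
  is not treated as an exact reproduction target.
- Cox regression, multiple-testing control beyond optional BH, PWM/log-odds
  motif scoring and de novo repeat detection are out of scope.
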