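# pprealu

Discovery of PPAR-responsive elements (PPREs) embedded in a distinctive
Alu-repeat promoter architecture, with the downstream cancer statistics that
motivate caring about them.

## The problem

PPARγ is a ligand-activated nuclear receptor that, as a heterodimer with
RXR, binds PPREs in the promoters of its target genes; the canonical site is
built from the DR1 half-site, and the heptamer instance studied here is
`TGACCTC`. The promoter of the maintenance methyltransferase gene *DNMT1*
carries such a PPRE inside the **left arm of an Alu element**, directly next
to the Alu's internal RNA polymerase III **B-box**, and that Alu sits in an
ordered run of repeats — `Alu, Alu, Low_complexity, LINE/L1` — within a few
hundred bp of each other. This package implements, as a tested reusable
pipeline, the computations needed to find and characterize that
architecture and to ask whether PPARγ–*DNMT1* regulation looks disturbed in
tumors:

1. **Promoter scanning** (`pprealu.promoter_scan`) — extract 4 kb / 2 kb
   windows upstream of each TSS, match the ordered repeat-configuration
   grammar (gap cap 500 bp between consecutive elements), scan the PPRE
   motif on both strands, and map each hit onto the Alu consensus
   (arm, A-/B-box proximity) by global alignment.
2. **Alu subfamily consensus and phylogeny** (`pprealu.alu_consensus`) —
   redundancy collapse by greedy identity clustering, Needleman–Wunsch
   global alignment, deterministic star MSA, majority consensus with
   per-column information content (2 − H bits), p-distance / Kimura-2P
   matrices, Saitou–Nei neighbor joining, nearest-subfamily assignment.
3. **Cancer statistics** (`pprealu.cancer_stats`) — per-cohort Pearson
   correlation of *PPARG*/*DNMT1* expression with t-based significance
   (t = r√(n−2)/√(1−r²)) and the weak-correlation band (−0.5 < r < 0.5);
   two-sample Kolmogorov–Smirnov comparison of observed variant
   evolutionary-action (EA) scores against the brute-force null of all
   missense single-nucleotide changes; median-split Kaplan–Meier survival
   S(t) = Π(1 − dᵢ/nᵢ) with the two-group log-rank test, overall and within
   chromosome-3 (disomy/monosomy) subgroups of an uveal-melanoma-like
   cohort.
4. **Synthetic data with planted truth** (`pprealu.synthetic_data`) — every
   input the pipeline consumes can be generated with known ground truth
   (planted configurations and motif positions, chosen latent correlations,
   score-band enrichment, group hazards), so each stage is verifiable
   end-to-end without downloads.

Formats in and out are the field's plain-text standards: FASTA,
RepeatMasker `.out`, BED6(+1), TSV/CSV, newick. All coordinates are 0-based
half-open.

## Worked example

Run the numbered analyses (each a thin driver over the library):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_scan_promoters.py
```

which prints, for the default seed-1 simulation:

```
genome: 400000 bp, 50 genes, 10 planted configurations, 54 repeat annotations
...
4000 bp windows: 10 qualifying genes (sensitivity 1.00, 0 false positives)
2000 bp windows: 10 qualifying genes (sensitivity 1.00, 0 false positives)
motif hits inside Alu copies: 10; left arm next to B-box: 10
```

i.e. the scanner recovers exactly the ten genes whose promoters carry the
planted configuration, no others, and places every planted heptamer in the
Alu left arm adjacent to the B-box. The remaining drivers
(`03_alu_subfamilies.py` … `06_uveal_survival.py`) rebuild the subfamily
consensi and their NJ tree from the genomic copies, and print, e.g.:

```
SYN1/control: n=60, r=0.846 [0.754, 0.905], p=1.82e-17 -> strong
SYN1/tumor: n=300, r=0.068 [-0.046, 0.179], p=0.244 -> weak (-0.5 < r < 0.5)
...
KS: D=0.2510, p=1.51e-05 -> the observed score distribution departs from random nucleotide changes
...
all: n=40+40, log-rank chi2=11.383, p=0.0007
```

— strong control / disturbed tumor co-expression, a variant-score
distribution skewed into the 60–80 band relative to all possible missense
changes, and a survival split by expression group. Tables and the KM plot
land under `results/`.

The same stages are available as a CLI
(`pprealu all|simulate|scan|consensus|assign|coexpr|ea-compare|survival`),
e.g.:

```bash
pprealu all --outdir report --seed 1
pprealu scan --genome g.fa --repeats rmsk.bed --tss tss.bed --window 2000 --out scan_out
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. Every run
writes a `manifest.json` with the seed, parameters and input checksums.

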