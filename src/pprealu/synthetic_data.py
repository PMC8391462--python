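"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's inputs: a
genome whose designated promoters carry the ordered repeat configuration
Alu-Alu-Low_complexity-LINE/L1 with the PPRE heptamer TGACCTC written into
the left arm of the first Alu next to its B-box; Alu copies mutated from
bundled synthetic subfamily consensi; tumor/control expression pairs with a
chosen latent Pearson correlation; observed mutation sets enriched in a
chosen evolutionary-action score band against the brute-force null of all
missense single-nucleotide changes; and survival cohorts whose hazard
depends on the expression group.

Everything is driven by ``numpy.random.default_rng`` (PCG64, integer state),
so a fixed config reproduces byte-identical outputs on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeSequence,
    RepeatFeature,
    TssRecord,
    reverse_complement,
    write_fasta,
    write_repeat_bed,
    write_tss_bed,
)
from .promoter_scan import DEFAULT_BOXES, PPRE_MOTIF, BoxCoords

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# The planted heptamer sits at this offset of the first Alu copy: inside the
# left arm, ending 3 bp before the default B-box at [72, 101).
PLANT_CONSENSUS_OFFSET = 62


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionParams:
    n_tumor: int = 300
    n_control: int = 60
    r_tumor: float = 0.1
    r_control: float = 0.9

    def __post_init__(self) -> None:
        for r in (self.r_tumor, self.r_control):
            if not -1 < r < 1:
                raise ValueError(f"correlation must be in (-1, 1), got {r}")


@dataclass(frozen=True)
class MutationParams:
    n_observed: int = 107
    score_band: tuple[float, float] = (60.0, 80.0)
    band_fraction: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = self.score_band
        if not (0 <= lo <= hi <= 100):
            raise ValueError("score_band must be within [0, 100]")
        if not 0 <= self.band_fraction <= 1:
            raise ValueError("band_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SurvivalParams:
    n_cases: int = 80
    frac_monosomy3: float = 31 / 80
    hazard_low: float = 0.18   # events per year, low-expression group
    hazard_high: float = 0.06  # events per year, high-expression group
    censor_time: float = 12.0  # years

    def __post_init__(self) -> None:
        if self.hazard_low <= 0 or self.hazard_high <= 0:
            raise ValueError("hazards must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic inputs; same config => identical outputs."""

    seed: int = 0
    chrom_length: int = 400_000
    n_genes: int = 50
    n_planted_configs: int = 10
    alu_mutation_rate: float = 0.05
    intergene_spacing: int = 7_000
    promoter_window: int = 2_000
    max_gap: int = 500
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    mutations: MutationParams = field(default_factory=MutationParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        if min(self.chrom_length, self.n_genes, self.n_planted_configs) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.alu_mutation_rate < 1:
            raise ValueError("alu_mutation_rate must be in [0, 1)")
        if self.n_planted_configs > self.n_genes:
            raise ValueError("cannot plant more configurations than genes")


# ---------------------------------------------------------------------------
# Bundled synthetic repeat consensus library
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()

_FORBIDDEN = (PPRE_MOTIF, reverse_complement(PPRE_MOTIF))


def _scrub_motif(seq: str, rng: np.random.Generator) -> str:
    """Destroy every PPRE occurrence (either strand) by editing one base."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for pat in _FORBIDDEN:
            i = text.find(pat)
            if i >= 0:
                mid = i + len(pat) // 2
                alts = [b for b in "ACGT" if b != s[mid]]
                s[mid] = alts[int(rng.integers(len(alts)))]
                changed = True
                break
    return "".join(s)


def builtin_alu_library(n_subfamilies: int = 4, length: int = 300) -> dict[str, str]:
    """Synthetic Alu subfamily consensus library (not real Alu sequence).

    Subfamilies are derived from a common synthetic ancestor by ~10%
    substitution, giving ~15-20% pairwise divergence — the regime where
    nearest-consensus assignment is unambiguous for copies mutated at <=10%.
    The PPRE heptamer is scrubbed from both strands of every consensus so
    that motif occurrences in simulated genomes are exactly the planted
    ones.  Generated from a fixed internal seed; stable across sessions.
    """
    rng = np.random.default_rng(195903)
    ancestor = _random_dna(rng, length)
    names = ["AluJ-syn", "AluSx-syn", "AluSz-syn", "AluY-syn", "AluJo-syn"]
    lib = {}
    for name in names[:n_subfamilies]:
        seq = _mutate(ancestor, 0.10, rng, protect=())
        lib[name] = _scrub_motif(seq, rng)
    return lib


def builtin_l1_fragment(length: int = 400) -> str:
    """Synthetic LINE/L1 fragment consensus (not real L1 sequence)."""
    rng = np.random.default_rng(195904)
    return _scrub_motif(_random_dna(rng, length), rng)


def _mutate(seq: str, rate: float, rng: np.random.Generator, protect: tuple[int, int] | tuple = ()) -> str:
    """Per-base substitution at the given rate, sparing ``protect`` [lo, hi)."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if protect:
        hit[protect[0]:protect[1]] = False
    idx = np.flatnonzero(hit)
    for i in idx:
        alts = _BASES[_BASES != arr[i]]
        arr[i] = alts[int(rng.integers(3))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Genome with planted configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedConfig:
    """Ground truth for one planted configuration."""

    gene_id: str
    elements: tuple[RepeatFeature, ...]
    ppre_genomic_start: int
    ppre_strand: str
    ppre_window_offset: int
    ppre_consensus_offset: int
    subfamilies: tuple[str, str]


@dataclass(frozen=True)
class PlantedTruth:
    configs: tuple[PlantedConfig, ...]

    @property
    def gene_ids(self) -> list[str]:
        return sorted(c.gene_id for c in self.configs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.configs:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "ppre_genomic_start": c.ppre_genomic_start,
                    "ppre_strand": c.ppre_strand,
                    "ppre_window_offset": c.ppre_window_offset,
                    "ppre_consensus_offset": c.ppre_consensus_offset,
                    "subfamilies": ";".join(c.subfamilies),
                    "elements": ";".join(
                        f"{e.class_family}:{e.start}-{e.end}" for e in c.elements
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "ppre_genomic_start", "ppre_strand", "ppre_window_offset",
                "ppre_consensus_offset", "subfamilies", "elements",
            ],
        )


@dataclass(frozen=True)
class SyntheticGenome:
    genome: GenomeSequence
    repeats: list[RepeatFeature]
    tss: list[TssRecord]
    truth: PlantedTruth

    def write_outputs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "repeats": outdir / "repeats.bed",
            "tss": outdir / "tss.bed",
            "truth": outdir / "planted_truth.tsv",
        }
        write_fasta([self.genome], paths["genome"])
        write_repeat_bed(self.repeats, paths["repeats"])
        write_tss_bed(self.tss, paths["tss"])
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_genome_with_annotations(
    config: SimulationConfig,
    alu_consensus_library: dict[str, str] | None = None,
    boxes: BoxCoords = DEFAULT_BOXES,
    chrom_id: str = "chrS1",
) -> SyntheticGenome:
    """Generate a genome whose planted promoters carry the full configuration.

    Background sequence is i.i.d. uniform over ACGT.  Genes alternate +/-
    strand on a regular spacing; each planted gene's promoter window gets, in
    5'->3' order, two Alu copies (consensus mutated at ``alu_mutation_rate``,
    the heptamer region of the first copy protected), a (TA)n low-complexity
    run and an L1 fragment, with inter-element gaps uniform on [1, max_gap]
    redrawn until the span fits the window.  The heptamer is written at
    consensus offset 62 of the first Alu — inside the left arm, adjacent to
    the B-box — on the reverse-complement strand for alternating plants.
    Every placed element is annotated; decoy lone Alus are dropped into some
    unplanted promoters as negative controls.
    """
    lib = alu_consensus_library if alu_consensus_library is not None else builtin_alu_library()
    if not lib:
        raise ValueError("empty Alu consensus library")
    rng = np.random.default_rng(config.seed)
    W = config.promoter_window
    if config.intergene_spacing < 2 * W:
        raise ValueError("intergene_spacing must be at least twice the promoter window")
    need = config.n_genes * config.intergene_spacing
    if need > config.chrom_length:
        raise ValueError(
            f"chrom_length {config.chrom_length} too short for {config.n_genes} genes "
            f"at spacing {config.intergene_spacing}"
        )

    seq = np.frombuffer(_random_dna(rng, config.chrom_length).encode(), dtype=np.uint8).copy()
    lib_names = sorted(lib)
    l1 = builtin_l1_fragment()
    low_complexity = "TA" * 25

    planted_idx = set(
        int(i) for i in rng.choice(config.n_genes, size=config.n_planted_configs, replace=False)
    )
    unplanted = [i for i in range(config.n_genes) if i not in planted_idx]
    decoy_idx = set(unplanted[::3])

    tss_records: list[TssRecord] = []
    repeats: list[RepeatFeature] = []
    planted: list[PlantedConfig] = []
    plant_counter = 0

    for gi in range(config.n_genes):
        slot = gi * config.intergene_spacing
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi:03d}"
        if strand == "+":
            tss = slot + W
            win_start, win_end = slot, slot + W
        else:
            tss = slot + W - 1
            win_start, win_end = slot + W, slot + 2 * W
        tss_records.append(TssRecord(gene_id, chrom_id, strand, tss))

        def place(win_off: int, elem_seq: str, name: str, cf: str) -> RepeatFeature:
            """Write an element at a window offset; returns its annotation."""
            L = len(elem_seq)
            if strand == "+":
                g0 = win_start + win_off
                seq[g0 : g0 + L] = np.frombuffer(elem_seq.encode(), dtype=np.uint8)
            else:
                g0 = win_end - win_off - L
                seq[g0 : g0 + L] = np.frombuffer(
                    reverse_complement(elem_seq).encode(), dtype=np.uint8
                )
            return RepeatFeature(chrom_id, g0, g0 + L, strand, name, cf)

        if gi in planted_idx:
            sf_a, sf_b = (
                lib_names[int(rng.integers(len(lib_names)))],
                lib_names[int(rng.integers(len(lib_names)))],
            )
            copy_a = _mutate(
                lib[sf_a], config.alu_mutation_rate, rng,
                protect=(PLANT_CONSENSUS_OFFSET, PLANT_CONSENSUS_OFFSET + len(PPRE_MOTIF)),
            )
            motif_rc = plant_counter % 2 == 1
            heptamer = reverse_complement(PPRE_MOTIF) if motif_rc else PPRE_MOTIF
            copy_a = (
                copy_a[:PLANT_CONSENSUS_OFFSET]
                + heptamer
                + copy_a[PLANT_CONSENSUS_OFFSET + len(PPRE_MOTIF):]
            )
            copy_b = _mutate(lib[sf_b], config.alu_mutation_rate, rng)
            elems = [
                (copy_a, sf_a, "SINE/Alu"),
                (copy_b, sf_b, "SINE/Alu"),
                (low_complexity, "(TA)n", "Low_complexity"),
                (l1, "L1-syn", "LINE/L1"),
            ]
            total_len = sum(len(e[0]) for e in elems)
            while True:
                gaps = [int(rng.integers(1, config.max_gap + 1)) for _ in range(3)]
                span = total_len + sum(gaps)
                if span <= W:
                    break
            start_off = int(rng.integers(0, W - span + 1))
            feats = []
            off = start_off
            for k, (eseq, name, cf) in enumerate(elems):
                feats.append(place(off, eseq, name, cf))
                off += len(eseq)
                if k < 3:
                    off += gaps[k]
            repeats.extend(feats)
            ppre_win_off = start_off + PLANT_CONSENSUS_OFFSET
            alu1 = feats[0]
            if strand == "+":
                g_ppre = win_start + ppre_win_off
                g_strand = "-" if motif_rc else "+"
            else:
                g_ppre = win_end - ppre_win_off - len(PPRE_MOTIF)
                g_strand = "+" if motif_rc else "-"
            planted.append(
                PlantedConfig(
                    gene_id=gene_id,
                    elements=tuple(feats),
                    ppre_genomic_start=g_ppre,
                    ppre_strand=g_strand,
                    ppre_window_offset=ppre_win_off,
                    ppre_consensus_offset=PLANT_CONSENSUS_OFFSET,
                    subfamilies=(sf_a, sf_b),
                )
            )
            plant_counter += 1
        elif gi in decoy_idx:
            sf = lib_names[int(rng.integers(len(lib_names)))]
            decoy = _mutate(lib[sf], config.alu_mutation_rate, rng)
            off = int(rng.integers(0, W - len(decoy) + 1))
            repeats.append(place(off, decoy, sf, "SINE/Alu"))

    genome = GenomeSequence(chrom_id, seq.tobytes().decode())
    return SyntheticGenome(genome, repeats, tss_records, PlantedTruth(tuple(planted)))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression_pair(
    config: SimulationConfig,
    cancer_type: str = "SYN1",
    genes: tuple[str, str] = ("PPARG", "DNMT1"),
) -> pd.DataFrame:
    """Two-gene expression for a tumor and a control cohort.

    Per cohort, samples are bivariate standard normal with the configured
    population correlation on the latent scale, then exponentiated (scaled
    to an FPKM-like range) so values are positive and right-skewed.  The
    planted correlation is therefore exact on ``log`` of the output.
    """
    e = config.expression
    if min(e.n_tumor, e.n_control) < 3:
        raise ValueError("need at least 3 samples per cohort")
    rng = np.random.default_rng(config.seed + 1)
    frames = []
    for cohort, n, r in (("control", e.n_control, e.r_control), ("tumor", e.n_tumor, e.r_tumor)):
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
        fpkm = np.exp(2.0 + z)
        frames.append(
            pd.DataFrame(
                {
                    "sample": [f"{cancer_type}-{cohort[0].upper()}{i:04d}" for i in range(n)],
                    "cancer_type": cancer_type,
                    "cohort": cohort,
                    genes[0]: fpkm[:, 0],
                    genes[1]: fpkm[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Mutations and EA-like scores
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def enumerate_missense_changes(cds: str) -> list[tuple[int, str, str, str]]:
    """All single-nucleotide missense changes of a CDS, by brute force.

    Every position x 3 alternative bases is tried; a change is missense when
    the mutant codon translates to a different amino acid that is not a stop.
    Returns (position, ref, alt, label) tuples in deterministic order.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    out = []
    for pos in range(len(cds)):
        ci = pos // 3
        codon = cds[3 * ci : 3 * ci + 3]
        aa = _CODON_TABLE[codon]
        for alt in "ACGT":
            if alt == cds[pos]:
                continue
            mut = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
            maa = _CODON_TABLE[mut]
            if maa != aa and maa != "*" and aa != "*":
                out.append((pos, cds[pos], alt, f"{aa}{ci + 1}{maa}"))
    return out


def random_score_table(cds: str, seed: int = 0) -> dict[tuple[int, str], float]:
    """Pseudo-random stand-in scores in [0, 100] for every missense change."""
    rng = np.random.default_rng(seed)
    return {
        (pos, alt): float(rng.uniform(0, 100))
        for pos, _, alt, _ in enumerate_missense_changes(cds)
    }


def generate_mutation_sets(
    config: SimulationConfig,
    cds_sequence: str,
    score_table: dict[tuple[int, str], float],
    gene: str = "GENE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs null mutation score sets.

    The null is the score of every possible missense single-nucleotide
    change of the CDS.  The observed set holds ``n_observed`` draws, a
    ``band_fraction`` of them restricted to ``score_band`` and the rest
    drawn uniformly from the null, emulating a variant catalogue skewed
    toward a pathogenicity band.
    """
    m = config.mutations
    changes = enumerate_missense_changes(cds_sequence)
    null_rows = [
        {"gene": gene, "variant": label, "ea_score": score_table[(pos, alt)]}
        for pos, _, alt, label in changes
    ]
    null = pd.DataFrame(null_rows, columns=["gene", "variant", "ea_score"])
    if null.empty:
        raise ValueError("CDS admits no missense changes")
    lo, hi = m.score_band
    band = null[(null.ea_score >= lo) & (null.ea_score <= hi)]
    rng = np.random.default_rng(config.seed + 2)
    n_band = int(round(m.band_fraction * m.n_observed))
    if n_band and band.empty:
        raise ValueError("score band contains no attainable scores for this CDS")
    picks = []
    if n_band:
        picks.append(band.iloc[rng.integers(0, len(band), size=n_band)])
    if m.n_observed - n_band:
        picks.append(null.iloc[rng.integers(0, len(null), size=m.n_observed - n_band)])
    observed = pd.concat(picks, ignore_index=True) if picks else null.iloc[:0].copy()
    return observed, null


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival_cohort(config: SimulationConfig) -> pd.DataFrame:
    """A survival cohort whose hazard depends on the expression group.

    Expression is continuous (log-normal); cases above the median form the
    high-expression group with hazard ``hazard_high``, the rest get
    ``hazard_low``; exponential event times are right-censored at
    ``censor_time``; chromosome-3 class is Bernoulli(frac_monosomy3).
    """
    s = config.survival
    if s.n_cases < 4:
        raise ValueError("need at least 4 cases")
    rng = np.random.default_rng(config.seed + 3)
    expr = np.exp(rng.normal(1.0, 0.6, size=s.n_cases))
    high = expr > np.median(expr)
    hazard = np.where(high, s.hazard_high, s.hazard_low)
    t = rng.exponential(1.0 / hazard)
    event = (t <= s.censor_time).astype(int)
    time = np.minimum(t, s.censor_time)
    time = np.maximum(time, 1e-9)
    chr3 = np.where(rng.random(s.n_cases) < s.frac_monosomy3, "monosomy3", "disomy3")
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "expression": expr,
            "chr3_class": chr3,
        }
    )
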