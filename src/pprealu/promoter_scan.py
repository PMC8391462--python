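"""Promoter-window extraction, repeat-configuration matching and PPRE scanning.

The discovery computation: take a window upstream of each TSS, find ordered
runs of annotated repeats matching a configuration grammar (by default
SINE/Alu, SINE/Alu, Low_complexity, LINE/L1 with <= 500 bp between
consecutive elements), locate PPRE motif occurrences (the DR1 half-site
heptamer TGACCTC on either strand), and place each motif hit inside the
dimeric Alu structure (left/right arm, proximity to the internal Pol III
A/B boxes) by aligning the genomic Alu copy back to its subfamily consensus.

Window coordinate 0 is always the position farthest upstream of the TSS, so
minus-strand windows carry the reverse-complemented reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .alu_consensus import GAP, align_pair
from .io_formats import (
    GenomeSequence,
    RepeatFeature,
    TssRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

PPRE_MOTIF = "TGACCTC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def motif_reverse_complement(motif: str) -> str:
    return motif.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class BoxCoords:
    """Structural landmarks on an Alu subfamily consensus (0-based half-open).

    Defaults follow the canonical dimeric Alu layout: a ~132 bp left (FLAM)
    arm carrying the internal RNA polymerase III A-box and B-box, an A-rich
    linker, then the right arm.
    """

    a_box: tuple[int, int] = (6, 32)
    b_box: tuple[int, int] = (72, 101)
    left_arm_end: int = 132
    linker_end: int = 158
    adjacency_bp: int = 10


DEFAULT_BOXES = BoxCoords()


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter window oriented 5'->3' of its gene.

    ``start``/``end`` are genomic (0-based half-open); ``seq`` is the window
    sequence with position 0 farthest upstream, i.e. the reverse complement
    of the reference slice for minus-strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    window_length: int
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("window sequence length does not match its interval")
        if self.end - self.start > self.window_length:
            raise ValueError("window longer than the requested length")

    def to_window_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval into window coordinates (5'->3' of gene)."""
        if self.strand == "+":
            return start - self.start, end - self.start
        return self.end - end, self.end - start

    def to_genomic_pos(self, offset: int, length: int = 1) -> int:
        """Genomic start of a window-coordinate interval [offset, offset+length)."""
        if self.strand == "+":
            return self.start + offset
        return self.end - offset - length


def extract_promoter_windows(
    genomes: dict[str, GenomeSequence] | list[GenomeSequence],
    tss_records: list[TssRecord],
    window_length: int = 4000,
) -> list[PromoterWindow]:
    """Cut the upstream window of each TSS, clipping at contig bounds.

    Plus-strand genes get [tss - L, tss); minus-strand genes get
    [tss + 1, tss + 1 + L) with the sequence reverse complemented so window
    coordinate 0 is farthest upstream in both cases.
    """
    if isinstance(genomes, list):
        genomes = {g.chrom_id: g for g in genomes}
    windows = []
    for t in tss_records:
        if t.chrom not in genomes:
            raise KeyError(f"TSS {t.gene_id} on unknown contig {t.chrom!r}")
        contig = genomes[t.chrom]
        if t.tss >= len(contig):
            raise ValueError(f"TSS {t.gene_id} at {t.tss} beyond contig end {len(contig)}")
        if t.strand == "+":
            start, end = max(0, t.tss - window_length), t.tss
            seq = contig.seq[start:end]
        else:
            start = t.tss + 1
            end = min(len(contig), start + window_length)
            seq = reverse_complement(contig.seq[start:end])
        if end - start < window_length:
            logger.warning(
                "promoter window of %s clipped to %d bp at contig edge",
                t.gene_id, end - start,
            )
        if end <= start:
            logger.warning("gene %s has an empty promoter window; skipped", t.gene_id)
            continue
        windows.append(PromoterWindow(t.gene_id, t.chrom, start, end, t.strand, window_length, seq))
    return windows


# ---------------------------------------------------------------------------
# Configuration grammar matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfigurationGrammar:
    """An ordered repeat-class pattern with a gap cap between elements."""

    terms: tuple[str, ...] = ("SINE/Alu", "SINE/Alu", "Low_complexity", "LINE/L1")
    max_gap: int = 500
    orientation_policy: str = "any"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("grammar needs at least one term")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.orientation_policy not in ("any", "same_strand"):
            raise ValueError(f"unknown orientation policy {self.orientation_policy!r}")

    @classmethod
    def from_string(cls, pattern: str, max_gap: int = 500, orientation_policy: str = "any"):
        terms = tuple(t.strip() for t in pattern.split(",") if t.strip())
        return cls(terms, max_gap, orientation_policy)


DEFAULT_GRAMMAR = ConfigurationGrammar()


@dataclass(frozen=True)
class ConfigurationMatch:
    """One assignment of window repeats to grammar terms, in 5'->3' order."""

    gene_id: str
    elements: tuple[RepeatFeature, ...]
    gaps: tuple[int, ...]
    window: PromoterWindow

    def alu_elements(self) -> tuple[RepeatFeature, ...]:
        return tuple(e for e in self.elements if e.class_family == "SINE/Alu")


def window_repeats(window: PromoterWindow, repeats: list[RepeatFeature]) -> list[RepeatFeature]:
    """Repeats overlapping the window by >= 1 bp, on the window's contig."""
    return [
        r for r in repeats
        if r.chrom == window.chrom and r.start < window.end and r.end > window.start
    ]


def match_configuration(
    window: PromoterWindow,
    repeats: list[RepeatFeature],
    grammar: ConfigurationGrammar = DEFAULT_GRAMMAR,
) -> list[ConfigurationMatch]:
    """All ordered assignments of window-overlapping repeats to grammar terms.

    Elements must appear at strictly increasing window coordinate; the gap
    from one element's end to the next element's start (window coordinates,
    which is the genomic gap regardless of strand) must not exceed
    ``max_gap``; under ``same_strand`` all elements share a strand.  Every
    valid assignment is reported, in deterministic (position) order.
    """
    overlapping = window_repeats(window, repeats)
    annotated = sorted(
        ((window.to_window_interval(r.start, r.end), r) for r in overlapping),
        key=lambda x: (x[0][0], x[0][1], x[1].name),
    )
    out: list[ConfigurationMatch] = []
    k = len(grammar.terms)

    def extend(idx: int, chosen: list[tuple[tuple[int, int], RepeatFeature]]) -> None:
        if len(chosen) == k:
            gaps = tuple(
                chosen[i + 1][0][0] - chosen[i][0][1] for i in range(k - 1)
            )
            out.append(
                ConfigurationMatch(
                    window.gene_id, tuple(r for _, r in chosen), gaps, window
                )
            )
            return
        term = grammar.terms[len(chosen)]
        for nxt in range(idx, len(annotated)):
            (ws, we), r = annotated[nxt]
            if r.class_family != term:
                continue
            if chosen:
                (pws, pwe), prev = chosen[-1]
                if ws <= pws:
                    continue
                if ws - pwe > grammar.max_gap:
                    continue
                if grammar.orientation_policy == "same_strand" and r.strand != prev.strand:
                    continue
            extend(nxt + 1, chosen + [((ws, we), r)])

    extend(0, [])
    return out


# ---------------------------------------------------------------------------
# PPRE motif scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PpreHit:
    """A PPRE motif occurrence with its genomic placement and Alu context.

    ``strand`` is the match strand relative to the reference; ``arm`` and
    ``adjacent_box`` are filled in by :func:`annotate_alu_context` once the
    hit has been located inside an annotated Alu copy.
    """

    gene_id: str
    chrom: str
    genomic_start: int
    genomic_end: int
    strand: str
    window_offset: int
    matched_text: str
    containing_alu: RepeatFeature | None = None
    consensus_offset: int | None = None
    arm: str = "none"
    adjacent_box: str = "none"


def _iupac_match_at(seq: str, pos: int, motif: str) -> bool:
    for k, mc in enumerate(motif):
        sc = seq[pos + k]
        if sc == "N" or sc not in IUPAC[mc]:
            return False
    return True


def scan_ppre(
    window: PromoterWindow,
    motif: str = PPRE_MOTIF,
    search_both_strands: bool = True,
) -> list[PpreHit]:
    """All occurrences of the motif (and its reverse complement) in a window.

    Overlapping occurrences are all reported; an N in the sequence never
    matches any motif symbol, including N itself.  Hit strand is relative to
    the reference: a forward-orientation match in a minus-strand window is a
    minus-strand hit genomically.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    for mc in motif:
        if mc not in IUPAC:
            raise ValueError(f"non-IUPAC motif symbol {mc!r}")
    patterns = [(motif, "+")]
    rc = motif_reverse_complement(motif)
    if search_both_strands:
        patterns.append((rc, "-"))
    if rc == motif and search_both_strands:
        patterns = [(motif, "+")]  # palindromic motif: one strand suffices

    seq = window.seq
    m = len(motif)
    hits = []
    for pat, rel_strand in patterns:
        for pos in range(len(seq) - m + 1):
            if _iupac_match_at(seq, pos, pat):
                genomic_strand = rel_strand if window.strand == "+" else ("-" if rel_strand == "+" else "+")
                gstart = window.to_genomic_pos(pos, m)
                hits.append(
                    PpreHit(
                        gene_id=window.gene_id,
                        chrom=window.chrom,
                        genomic_start=gstart,
                        genomic_end=gstart + m,
                        strand=genomic_strand,
                        window_offset=pos,
                        matched_text=seq[pos : pos + m],
                    )
                )
    hits.sort(key=lambda h: (h.window_offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Alu-context annotation
# ---------------------------------------------------------------------------

def _map_through_alignment(aln_copy: str, aln_cons: str, copy_pos: int) -> int:
    """Map a position in the ungapped copy onto the consensus via alignment.

    Returns the consensus position aligned to the copy base, or the nearest
    preceding consensus position when the copy base sits in a consensus gap.
    """
    ci = -1  # consensus index of last consumed consensus char
    seen_copy = 0
    for a, b in zip(aln_copy, aln_cons):
        if b != GAP:
            ci += 1
        if a != GAP:
            if seen_copy == copy_pos:
                return max(ci, 0)
            seen_copy += 1
    return max(ci, 0)


def _interval_distance(pos_start: int, pos_end: int, box: tuple[int, int]) -> int:
    if pos_end <= box[0]:
        return box[0] - pos_end + 1
    if pos_start >= box[1]:
        return pos_start - box[1] + 1
    return 0


def annotate_alu_context(
    hit: PpreHit,
    repeats: list[RepeatFeature],
    consensus_library: dict[str, str],
    genome: GenomeSequence | dict[str, GenomeSequence],
    boxes: BoxCoords = DEFAULT_BOXES,
) -> PpreHit:
    """Locate a motif hit inside the Alu dimeric structure.

    If the hit lies inside an annotated SINE/Alu feature, the genomic copy is
    globally aligned to its subfamily consensus (by annotation name, falling
    back to the nearest library entry by alignment identity) and the hit
    start is mapped through the alignment onto consensus coordinates.  The
    arm is called from the mapped offset against the box coordinates, and
    A-/B-box adjacency uses the ``adjacency_bp`` cap (B-box wins a tie, being
    the landmark the configuration is anchored to).  Hits outside any Alu
    come back with arm='none'.
    """
    if isinstance(genome, dict):
        genome = genome[hit.chrom]
    alu = None
    for r in repeats:
        if (
            r.class_family == "SINE/Alu"
            and r.chrom == hit.chrom
            and r.start <= hit.genomic_start
            and hit.genomic_end <= r.end
        ):
            alu = r
            break
    if alu is None:
        return hit

    copy_seq = genome.seq[alu.start : alu.end]
    if alu.strand == "-":
        copy_seq = reverse_complement(copy_seq)
        pos_in_copy = alu.end - hit.genomic_end
    else:
        pos_in_copy = hit.genomic_start - alu.start

    if alu.name in consensus_library:
        cons = consensus_library[alu.name]
    else:
        best_name = max(
            sorted(consensus_library),
            key=lambda k: align_pair(copy_seq, consensus_library[k]).identity,
        )
        cons = consensus_library[best_name]

    aln = align_pair(copy_seq, cons)
    off = _map_through_alignment(aln.aligned_a, aln.aligned_b, pos_in_copy)
    off_end = off + (hit.genomic_end - hit.genomic_start)

    if off < boxes.left_arm_end:
        arm = "left"
    elif off < boxes.linker_end:
        arm = "linker"
    else:
        arm = "right"

    d_b = _interval_distance(off, off_end, boxes.b_box)
    d_a = _interval_distance(off, off_end, boxes.a_box)
    if d_b <= boxes.adjacency_bp:
        box = "B-box"
    elif d_a <= boxes.adjacency_bp:
        box = "A-box"
    else:
        box = "none"

    return replace(hit, containing_alu=alu, consensus_offset=off, arm=arm, adjacent_box=box)


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def genome_scan_similar(
    genomes: dict[str, GenomeSequence] | list[GenomeSequence],
    tss_records: list[TssRecord],
    repeats: list[RepeatFeature],
    grammar: ConfigurationGrammar = DEFAULT_GRAMMAR,
    motif: str = PPRE_MOTIF,
    window_length: int = 2000,
    consensus_library: dict[str, str] | None = None,
    boxes: BoxCoords = DEFAULT_BOXES,
) -> tuple[list[str], pd.DataFrame, list[ConfigurationMatch], list[PpreHit]]:
    """Scan every gene for the PPRE-in-Alu repeat configuration.

    A gene qualifies when its promoter window holds at least one grammar
    match AND at least one motif hit lying inside an Alu element of such a
    match.  Returns the sorted qualifying gene list, a per-gene report
    table, and the full match and annotated hit lists.
    """
    if isinstance(genomes, list):
        genomes = {g.chrom_id: g for g in genomes}
    windows = extract_promoter_windows(genomes, tss_records, window_length)
    qualifying: list[str] = []
    rows = []
    all_matches: list[ConfigurationMatch] = []
    all_hits: list[PpreHit] = []
    for w in windows:
        matches = match_configuration(w, repeats, grammar)
        hits = scan_ppre(w, motif)
        if consensus_library:
            local = window_repeats(w, repeats)
            hits = [
                annotate_alu_context(h, local, consensus_library, genomes[w.chrom], boxes)
                for h in hits
            ]
        alus_in_matches = {
            (e.start, e.end) for m in matches for e in m.alu_elements()
        }
        hits_in_alu = [
            h for h in hits
            if any(s <= h.genomic_start and h.genomic_end <= e for s, e in alus_in_matches)
        ]
        qualifies = bool(matches) and bool(hits_in_alu)
        if qualifies:
            qualifying.append(w.gene_id)
        rows.append(
            {
                "gene_id": w.gene_id,
                "chrom": w.chrom,
                "strand": w.strand,
                "window_start": w.start,
                "window_end": w.end,
                "n_matches": len(matches),
                "n_ppre_hits": len(hits),
                "n_hits_in_matched_alu": len(hits_in_alu),
                "qualifies": qualifies,
            }
        )
        all_matches.extend(matches)
        all_hits.extend(hits)
    report = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "strand", "window_start", "window_end",
            "n_matches", "n_ppre_hits", "n_hits_in_matched_alu", "qualifies",
        ],
    ).sort_values("gene_id", kind="stable").reset_index(drop=True)
    return sorted(qualifying), report, all_matches, all_hits


def matches_to_frame(matches: list[ConfigurationMatch]) -> pd.DataFrame:
    rows = []
    for m in matches:
        rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.window.chrom,
                "elements": ";".join(
                    f"{e.name}:{e.start}-{e.end}({e.strand})" for e in m.elements
                ),
                "classes": ";".join(e.class_family for e in m.elements),
                "gaps": ";".join(str(g) for g in m.gaps),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "elements", "classes", "gaps"])
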