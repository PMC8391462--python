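"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: every interval in memory and in every output file is
0-based half-open, BED style.  RepeatMasker ``.out`` files (1-based inclusive)
are converted at parse time and never seen downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: identifier plus an uppercase sequence over {A,C,G,T,N}."""

    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("empty chrom_id")
        if not self.seq:
            raise ValueError(f"empty sequence for {self.chrom_id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene, contig, strand and 0-based position."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat interval with its class/family label."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    class_family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of :class:`GenomeSequence`.

    Lowercase is folded to uppercase and wrapped lines are joined.  Illegal
    characters or a record body before any header raise
    :class:`FastaFormatError` naming the line number.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if header is None:
            return
        if not chunks:
            raise FastaFormatError(f"{path}:{lineno}: record {header!r} has no sequence")
        records.append(GenomeSequence(header, "".join(chunks)))

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                up = line.upper()
                bad = set(up) - DNA_ALPHABET
                if bad:
                    raise FastaFormatError(
                        f"{path}:{lineno}: illegal character(s) {sorted(bad)}"
                    )
                chunks.append(up)
        _flush(lineno + 1)
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom_id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Repeat class vocabulary
# ---------------------------------------------------------------------------

def load_class_vocabulary() -> dict[str, str]:
    """Normalization table mapping raw class/family labels to canonical ones."""
    text = resources.files("pprealu.data").joinpath("repeat_classes.yaml").read_text()
    table = yaml.safe_load(text)
    return dict(table["classes"])


def normalize_class_family(raw: str, vocab: dict[str, str] | None = None) -> str:
    """Map a raw class/family label through the controlled vocabulary.

    Unknown labels pass through unchanged with a warning rather than failing,
    so exotic RepeatMasker classes do not abort a parse.
    """
    vocab = vocab if vocab is not None else load_class_vocabulary()
    if raw in vocab:
        return vocab[raw]
    logger.warning("unknown repeat class %r passed through unnormalized", raw)
    return raw


# ---------------------------------------------------------------------------
# Repeat annotations
# ---------------------------------------------------------------------------

def read_repeat_annotations(path: str | Path, dialect: str = "bed") -> list[RepeatFeature]:
    """Read repeat annotations from RepeatMasker ``.out`` or BED6+1.

    ``rmsk_out`` rows are 1-based inclusive and are shifted to 0-based
    half-open; RepeatMasker's ``C`` strand becomes ``-``.  BED6+1 carries the
    class/family in column 7 and is already 0-based half-open.  Rows whose
    interval is empty or inverted are dropped; their count is logged.
    """
    path = Path(path)
    if dialect == "rmsk_out":
        rows = _read_rmsk_out(path)
    elif dialect == "bed":
        rows = _read_repeat_bed(path)
    else:
        raise ValueError(f"unknown repeat annotation dialect {dialect!r}")

    vocab = load_class_vocabulary()
    feats: list[RepeatFeature] = []
    n_bad = 0
    for chrom, start, end, strand, name, cf in rows:
        if end <= start:
            n_bad += 1
            continue
        feats.append(
            RepeatFeature(chrom, start, end, strand, name, normalize_class_family(cf, vocab))
        )
    if n_bad:
        logger.warning("%s: dropped %d records with end <= start", path, n_bad)
    return feats


def _read_rmsk_out(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for raw in fh:
            parts = raw.split()
            if len(parts) < 11:
                continue
            try:
                begin, end = int(parts[5]), int(parts[6])
            except ValueError:
                continue  # header line
            chrom = parts[4]
            strand = "-" if parts[8] in ("C", "-") else "+"
            name, cf = parts[9], parts[10]
            rows.append((chrom, begin - 1, end, strand, name, cf))
    return rows


def _read_repeat_bed(path: Path) -> list[tuple]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand", "class_family"],
        dtype={"chrom": str, "name": str, "strand": str, "class_family": str},
    )
    return [
        (r.chrom, int(r.start), int(r.end), r.strand, r.name, r.class_family)
        for r in df.itertuples(index=False)
    ]


def write_repeat_bed(feats: Iterable[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in sorted(feats, key=lambda f: (f.chrom, f.start, f.end)):
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\t{f.class_family}\n"
            )


# ---------------------------------------------------------------------------
# TSS
# ---------------------------------------------------------------------------

def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read TSS records from BED6; the strand column is authoritative.

    The TSS position is ``start`` for + genes and ``end - 1`` for - genes
    (the interval's strand-aware first base).  gene_id must be unique.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    dup = df["name"][df["name"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id(s) in {path}: {sorted(set(dup))}")
    out = []
    for r in df.itertuples(index=False):
        tss = int(r.start) if r.strand == "+" else int(r.end) - 1
        out.append(TssRecord(r.name, r.chrom, r.strand, tss))
    return out


def write_tss_bed(records: Iterable[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in records:
            start = t.tss if t.strand == "+" else t.tss
            fh.write(f"{t.chrom}\t{start}\t{start + 1}\t{t.gene_id}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Report tables and hit output
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "gene_id",
    "chrom",
    "genomic_start",
    "genomic_end",
    "strand",
    "window_offset",
    "matched_text",
    "containing_alu",
    "consensus_offset",
    "arm",
    "adjacent_box",
]


def write_hits(hits: Sequence, path: str | Path, fmt: str = "tsv") -> None:
    """Write PPRE hits as BED6 or as a TSV with all Alu-context columns.

    Rows are sorted by (chrom, genomic start, gene_id) so output is
    deterministic regardless of scan order.
    """
    ordered = sorted(hits, key=lambda h: (h.chrom, h.genomic_start, h.gene_id))
    if fmt == "bed":
        with open(path, "w") as fh:
            for h in ordered:
                fh.write(
                    f"{h.chrom}\t{h.genomic_start}\t{h.genomic_end}\t"
                    f"{h.gene_id}:{h.matched_text}\t0\t{h.strand}\n"
                )
    elif fmt == "tsv":
        rows = []
        for h in ordered:
            rows.append(
                {
                    "gene_id": h.gene_id,
                    "chrom": h.chrom,
                    "genomic_start": h.genomic_start,
                    "genomic_end": h.genomic_end,
                    "strand": h.strand,
                    "window_offset": h.window_offset,
                    "matched_text": h.matched_text,
                    "containing_alu": h.containing_alu.name if h.containing_alu else "",
                    "consensus_offset": "" if h.consensus_offset is None else h.consensus_offset,
                    "arm": h.arm,
                    "adjacent_box": h.adjacent_box,
                }
            )
        pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown hit format {fmt!r}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as UTF-8 TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
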