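"""Alu subfamily consensus building and nearest-subfamily assignment.

This module is the computational substrate for turning a bag of genomic Alu
copies into per-subfamily consensus sequences and a distance-based phylogeny:
redundancy collapse, Needleman-Wunsch global alignment, a deterministic star
multiple alignment, majority-rule consensus with per-column information
content, p-distance (optionally Kimura 2-parameter) matrices, Saitou-Nei
neighbor joining, and nearest-consensus subfamily assignment.

Everything here is deterministic: alignment traceback ties prefer diagonal,
then up (gap in the second sequence), then left; consensus ties break
alphabetically; NJ join ties break on the lowest (row, column) index.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment: two equal-length gapped strings and the score."""

    aligned_a: str
    aligned_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def identity(self) -> float:
        """Matching positions divided by alignment length."""
        n = sum(a == b and a != GAP for a, b in zip(self.aligned_a, self.aligned_b))
        return n / len(self.aligned_a)


def align_pair(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with linear gap penalties.

    The dynamic-programming matrix is filled exactly; traceback ties are
    broken by preferring diagonal, then up (consume a base of ``a``), then
    left, which makes the alignment string deterministic.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    F[0, :] = np.arange(m + 1) * gap
    F[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mismatch)
        cand = np.maximum(F[i - 1, :-1] + sub, F[i - 1, 1:] + gap)
        row = F[i]
        prev = row[0]
        # left dependency is a sequential prefix scan
        for j in range(1, m + 1):
            prev = max(cand[j - 1], prev + gap)
            row[j] = prev
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = F[i, j]
        if i > 0 and j > 0 and here == F[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and here == F[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), int(F[n, m]))


# ---------------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------------

def collapse_redundancy(sequences: list[str], identity_threshold: float = 0.95) -> list[str]:
    """Greedy identity clustering; returns one representative per cluster.

    Sequences are processed in input order; each joins the first existing
    cluster whose representative it matches at >= threshold global identity
    (matches / alignment length), otherwise it founds a new cluster.  The
    representative is the first member, so the result is deterministic.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if not sequences:
        raise ValueError("no sequences to collapse")
    reps: list[str] = []
    for seq in sequences:
        for rep in reps:
            if seq == rep or align_pair(seq, rep).identity >= identity_threshold:
                break
        else:
            reps.append(seq)
    return reps


# ---------------------------------------------------------------------------
# Star multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    """Rows of equal-length gapped strings; row 0 order follows the input."""

    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def build_msa(sequences: list[str]) -> MultipleAlignment:
    """Deterministic star alignment around the most central sequence.

    The center is the sequence maximizing summed pairwise identity to all
    others (ties to the first).  Every other sequence is aligned pairwise to
    the center and gaps are merged under the once-a-gap-always-a-gap rule.
    Rows come back in input order.
    """
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        logger.warning("build_msa called with a single sequence")
        return MultipleAlignment((sequences[0],))

    n = len(sequences)
    pairwise = {}
    totals = [0.0] * n
    for i, j in itertools.combinations(range(n), 2):
        ident = align_pair(sequences[i], sequences[j]).identity
        pairwise[(i, j)] = ident
        totals[i] += ident
        totals[j] += ident
    center = max(range(n), key=lambda i: (totals[i], -i))

    c = sequences[center]
    # ins[k] = gap columns inserted before center position k (k = len(c) -> after end)
    ins = [0] * (len(c) + 1)
    aligned: dict[int, PairwiseAlignment] = {}
    for i in range(n):
        if i == center:
            continue
        aln = align_pair(c, sequences[i])
        aligned[i] = aln
        k = 0
        run = 0
        for ca in aln.aligned_a:
            if ca == GAP:
                run += 1
            else:
                ins[k] = max(ins[k], run)
                run = 0
                k += 1
        ins[len(c)] = max(ins[len(c)], run)

    def pad_center() -> str:
        out = []
        for k, base in enumerate(c):
            out.append(GAP * ins[k])
            out.append(base)
        out.append(GAP * ins[len(c)])
        return "".join(out)

    def pad_row(aln: PairwiseAlignment) -> str:
        out = []
        k = 0
        run: list[str] = []
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == GAP:
                run.append(cb)
            else:
                out.append("".join(run) + GAP * (ins[k] - len(run)))
                out.append(cb)
                run = []
                k += 1
        out.append("".join(run) + GAP * (ins[len(c)] - len(run)))
        return "".join(out)

    rows = []
    for i in range(n):
        rows.append(pad_center() if i == center else pad_row(aligned[i]))
    return MultipleAlignment(tuple(rows))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusResult:
    """Majority consensus plus the column-wise counts and information content.

    ``pfm`` has one row per retained column with counts over A,C,G,T and gap;
    ``info_content`` is 2 - H (bits) of the gap-excluded base frequencies.
    """

    consensus: str
    pfm: np.ndarray  # shape (n_columns, 5), columns A,C,G,T,-
    info_content: np.ndarray  # shape (n_columns,)
    retained_columns: tuple[int, ...]


def call_consensus(msa: MultipleAlignment, gap_column_threshold: float = 0.5) -> ConsensusResult:
    """Majority-rule consensus over MSA columns.

    Columns whose gap fraction exceeds the threshold are dropped.  Per
    retained column the consensus base is the majority over {A,C,G,T} with
    alphabetical tie-break, and the information content is 2 minus the
    Shannon entropy (bits) of the base frequencies with gaps excluded.
    """
    n_rows = len(msa.rows)
    cols = []
    consensus = []
    infos = []
    kept = []
    for j in range(msa.n_columns):
        column = [row[j] for row in msa.rows]
        counts = {b: column.count(b) for b in BASES}
        n_gap = column.count(GAP)
        if n_gap / n_rows > gap_column_threshold:
            continue
        kept.append(j)
        cols.append([counts["A"], counts["C"], counts["G"], counts["T"], n_gap])
        best = max(BASES, key=lambda b: (counts[b], -ord(b)))
        consensus.append(best)
        n_bases = n_rows - n_gap
        h = 0.0
        for b in BASES:
            p = counts[b] / n_bases
            if p > 0:
                h -= p * math.log2(p)
        infos.append(2.0 - h)
    if not kept:
        raise ValueError("all columns exceeded the gap threshold")
    return ConsensusResult(
        "".join(consensus),
        np.array(cols, dtype=int),
        np.array(infos, dtype=float),
        tuple(kept),
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric taxon-by-taxon distance matrix with a zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")


def _pair_distance(ra: str, rb: str, model: str) -> float:
    """Distance between two gapped rows over columns where both are non-gap."""
    n_sites = 0
    n_diff = 0
    n_ts = 0  # transitions, for K2P
    purines = {"A", "G"}
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP or x == "N" or y == "N":
            continue
        n_sites += 1
        if x != y:
            n_diff += 1
            if (x in purines) == (y in purines):
                n_ts += 1
    if n_sites == 0:
        raise ValueError("no comparable (non-gap) sites between sequences")
    p = n_diff / n_sites
    if model == "p":
        return p
    if model == "k2p":
        P = n_ts / n_sites
        Q = (n_diff - n_ts) / n_sites
        try:
            return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        except ValueError as exc:
            raise ValueError("K2P distance undefined (saturated divergence)") from exc
    raise ValueError(f"unknown distance model {model!r}")


def p_distance_matrix(
    sequences: list[str] | MultipleAlignment,
    labels: list[str] | None = None,
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise p-distances (or K2P with ``model='k2p'``).

    Accepts either an MSA (column-wise comparison over mutually non-gap
    sites) or raw sequences, which are then globally aligned pair by pair.
    """
    if isinstance(sequences, MultipleAlignment):
        rows = list(sequences.rows)
        aligned_pairs = None
    else:
        rows = list(sequences)
        aligned_pairs = {}
    n = len(rows)
    if n < 2:
        raise ValueError("need at least two taxa")
    if labels is None:
        labels = [f"seq{i}" for i in range(n)]
    m = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        if aligned_pairs is None:
            d = _pair_distance(rows[i], rows[j], model)
        else:
            aln = align_pair(rows[i], rows[j])
            d = _pair_distance(aln.aligned_a, aln.aligned_b, model)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(labels), m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJNode:
    label: str | None = None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))

    def newick_fragment(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick_fragment()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner})"


@dataclass
class NJTree:
    """Unrooted NJ tree (stored rooted at the final 3-degree internal node)."""

    root: NJNode
    labels: tuple[str, ...]
    negative_branches_clamped: int = 0

    def newick(self) -> str:
        return self.root.newick_fragment() + ";"

    def n_edges(self) -> int:
        def count(node: NJNode) -> int:
            return sum(1 + count(c) for c, _ in node.children)

        return count(self.root)

    def splits(self) -> dict[frozenset[str], float]:
        """Canonical bipartition -> branch length map for exact comparison.

        Each edge is keyed by the leaf set on the far side from a fixed
        reference leaf (the alphabetically smallest label), which is
        invariant to the arbitrary rooting of the unrooted tree.
        """
        all_leaves = frozenset(self.labels)
        ref = min(self.labels)
        out: dict[frozenset[str], float] = {}

        def walk(node: NJNode) -> None:
            for child, length in node.children:
                below = child.leaves()
                key = below if ref not in below else all_leaves - below
                out[key] = out.get(key, 0.0) + length
                walk(child)

        walk(self.root)
        return out


def nj_tree(dist: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion (ties to the lowest
    (row, column) index), with branch lengths from the standard NJ formulas;
    negative length estimates are clamped to zero and counted.  The last
    three nodes are joined at a single internal node, giving the usual
    unrooted binary tree with 2n-3 edges.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dist.matrix.astype(float).copy()
    nodes: list[NJNode] = [NJNode(label=l) for l in dist.labels]
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = clamp(0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))))
        new = NJNode(children=[(nodes[i], li), (nodes[j], lj)])
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for m_ in active:
            if m_ in (i, j):
                continue
            d = 0.5 * (D[i, m_] + D[j, m_] - D[i, j])
            D[k, m_] = D[m_, k] = d
        nodes.append(new)
        active = [m_ for m_ in active if m_ not in (i, j)] + [k]

    i, j, k = active
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root = NJNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return NJTree(root, dist.labels, clamped)


# ---------------------------------------------------------------------------
# Subfamily assignment
# ---------------------------------------------------------------------------

def assign_subfamily(
    candidate_sequence: str,
    consensus_library: dict[str, str],
    candidate_label: str = "candidate",
) -> tuple[str, float, NJTree | None]:
    """Assign a sequence to the nearest subfamily consensus by p-distance.

    The candidate is globally aligned to every consensus; the assignment is
    the minimum-distance subfamily (ties break alphabetically).  When the
    library holds >= 2 consensi an NJ tree of {candidate + consensi} is also
    returned for reporting; with a single consensus the tree is None.
    """
    if not consensus_library:
        raise ValueError("empty consensus library")
    dists = {}
    for name in sorted(consensus_library):
        aln = align_pair(candidate_sequence, consensus_library[name])
        dists[name] = _pair_distance(aln.aligned_a, aln.aligned_b, "p")
    best = min(sorted(dists), key=lambda k: dists[k])
    tree = None
    if len(consensus_library) >= 2:
        labels = [candidate_label] + sorted(consensus_library)
        seqs = [candidate_sequence] + [consensus_library[k] for k in sorted(consensus_library)]
        tree = nj_tree(p_distance_matrix(seqs, labels))
    return best, dists[best], tree
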