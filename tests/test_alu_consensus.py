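import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pprealu import alu_consensus as ac


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def nw_score_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Exhaustive recursion over all global alignments (tiny inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive lengths and its path-distance matrix.

    Returns (labels, matrix, splits) where splits maps each canonical
    bipartition (side not containing the alphabetically first taxon) to its
    total branch length, mirroring NJTree.splits().
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with edge lengths; start from a star on 3 leaves
    nodes = {f"t{i}" for i in range(3)}
    internal = ["x0"]
    adj = {"x0": {}}
    for i in range(3):
        ln = rng.uniform(0.1, 1.0)
        adj.setdefault(f"t{i}", {})["x0"] = ln
        adj["x0"][f"t{i}"] = ln
    for i in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        total = adj[u][v]
        cut = rng.uniform(0.2, 0.8) * total
        new_int = f"x{len(internal)}"
        internal.append(new_int)
        leaf = f"t{i}"
        del adj[u][v], adj[v][u]
        adj[new_int] = {}
        for a, ln in ((u, cut), (v, total - cut)):
            adj[new_int][a] = ln
            adj[a][new_int] = ln
        pln = rng.uniform(0.1, 1.0)
        adj[leaf] = {new_int: pln}
        adj[new_int][leaf] = pln

    # path distances by BFS/DFS
    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u].items():
                if v not in out:
                    out[v] = out[u] + ln
                    stack.append(v)
        return out

    m = np.zeros((n_taxa, n_taxa))
    for i, li in enumerate(labels):
        d = dists_from(li)
        for j, lj in enumerate(labels):
            m[i, j] = d[lj]
    m = (m + m.T) / 2  # wash out float round-off from per-row path sums

    # canonical splits: remove each edge, take the component's leaf set
    ref = min(labels)
    all_leaves = frozenset(labels)
    splits = {}
    for u in adj:
        for v, ln in adj[u].items():
            if u > v:
                continue
            # component containing u with edge (u, v) removed
            seen = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if (x, y) == (u, v) or (y, x) == (u, v):
                        continue
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(s for s in seen if s in all_leaves)
            key = side if ref not in side else all_leaves - side
            if key and key != all_leaves:
                splits[key] = splits.get(key, 0.0) + ln
    return labels, m, splits


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

class TestAlignPair:
    @pytest.mark.parametrize(
        "a,b,score",
        [("ACGT", "ACGT", 4), ("ACGT", "ACT", 1), ("A", "T", -1)],
    )
    def test_known_scores(self, a, b, score):
        aln = ac.align_pair(a, b)
        assert aln.score == score
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_known_alignment_string(self):
        aln = ac.align_pair("ACGT", "ACT")
        assert (aln.aligned_a, aln.aligned_b) == ("ACGT", "AC-T")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=5),
        st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_equals_exhaustive_enumeration(self, a, b):
        assert ac.align_pair(a, b).score == nw_score_oracle(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ac.align_pair("", "ACGT")


class TestCollapseRedundancy:
    def test_identical_sequences_collapse_to_one(self):
        assert ac.collapse_redundancy(["ACGTACGT"] * 5) == ["ACGTACGT"]

    def test_distant_pair_stays_apart(self):
        a, b = "AAAAAAAA", "AAAATTTT"  # 50% identity
        assert ac.collapse_redundancy([a, b], 0.95) == [a, b]

    def test_two_seed_clusters_partition_by_seed(self, rng):
        from pprealu.synthetic_data import _mutate

        seed_a = "".join(rng.choice(list("ACGT"), size=120))
        seed_b = "".join(
            c if rng.random() > 0.4 else rng.choice([x for x in "ACGT" if x != c])
            for c in seed_a
        )
        # 5% per copy => ~10% divergence within a seed, ~40%+ between seeds
        copies = [_mutate(seed_a, 0.05, rng) for _ in range(10)]
        copies += [_mutate(seed_b, 0.05, rng) for _ in range(10)]
        reps = ac.collapse_redundancy(copies, 0.8)
        assert len(reps) == 2
        assert reps[0] == copies[0] and reps[1] == copies[10]

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            ac.collapse_redundancy(["ACGT"], 1.5)


class TestMsa:
    def test_identical_rows_have_no_gap_columns(self):
        msa = ac.build_msa(["ACGTACGT"] * 3)
        assert all("-" not in r for r in msa.rows)

    def test_degapped_rows_recover_inputs(self):
        seqs = ["ACGT", "ACT", "AGT"]
        msa = ac.build_msa(seqs)
        assert msa.n_columns >= 4
        assert [msa.degapped(i) for i in range(3)] == seqs

    def test_substitution_only_copies_align_without_gaps(self, rng):
        from pprealu.synthetic_data import _mutate

        seed = "".join(rng.choice(list("ACGT"), size=300))
        copies = [_mutate(seed, 0.05, rng) for _ in range(10)]
        msa = ac.build_msa(copies)
        assert msa.n_columns == 300
        assert all("-" not in r for r in msa.rows)

    def test_single_sequence_returned_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            msa = ac.build_msa(["ACGT"])
        assert msa.rows == ("ACGT",)


class TestConsensus:
    def test_unanimous_alignment(self):
        res = ac.call_consensus(ac.MultipleAlignment(("ACGT",) * 4))
        assert res.consensus == "ACGT"
        assert np.allclose(res.info_content, 2.0)

    def test_tied_column_breaks_alphabetically_with_one_bit(self):
        msa = ac.MultipleAlignment(("A", "A", "C", "C"))
        res = ac.call_consensus(msa)
        assert res.consensus == "A"  # A vs C tie -> alphabetical
        assert res.info_content[0] == pytest.approx(1.0)  # H({1/2,1/2}) = 1 bit

    def test_gap_majority_columns_dropped(self):
        msa = ac.MultipleAlignment(("A-G", "A-G", "ACG", "A-G"))
        res = ac.call_consensus(msa, gap_column_threshold=0.5)
        assert res.consensus == "AG"
        assert res.retained_columns == (0, 2)

    def test_all_columns_dropped_is_an_error(self):
        with pytest.raises(ValueError):
            ac.call_consensus(ac.MultipleAlignment(("-", "-", "A")))

    def test_recovers_seed_from_mutated_copies(self, rng):
        from pprealu.synthetic_data import _mutate

        for _ in range(3):
            seed = "".join(rng.choice(list("ACGT"), size=300))
            copies = [_mutate(seed, 0.05, rng) for _ in range(20)]
            assert ac.call_consensus(ac.build_msa(copies)).consensus == seed

    def test_pfm_rows_sum_to_depth(self):
        msa = ac.build_msa(["ACGT", "ACT", "AGT"])
        res = ac.call_consensus(msa)
        assert (res.pfm.sum(axis=1) == 3).all()

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=8), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_info_content_bounds(self, seqs):
        res = ac.call_consensus(ac.build_msa(seqs))
        assert ((res.info_content >= -1e-12) & (res.info_content <= 2 + 1e-12)).all()
        # unanimity iff 2 bits
        for k, j in enumerate(res.retained_columns):
            col = {r[j] for r in ac.build_msa(seqs).rows} - {"-"}
            assert (len(col) == 1) == (res.info_content[k] > 2 - 1e-9)


class TestDistances:
    def test_identical_and_quarter_distance(self):
        dm = ac.p_distance_matrix(["AAAA", "AAAA", "AAAT"])
        assert dm.matrix[0, 1] == 0.0
        assert dm.matrix[0, 2] == pytest.approx(0.25)

    def test_matches_column_count_oracle(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(2)]
        msa = ac.MultipleAlignment(tuple(rows))
        diff = comp = 0
        for x, y in zip(*rows):
            if x != "-" and y != "-":
                comp += 1
                diff += x != y
        dm = ac.p_distance_matrix(msa)
        assert dm.matrix[0, 1] == pytest.approx(diff / comp)

    def test_no_comparable_sites_is_an_error(self):
        msa = ac.MultipleAlignment(("A-", "-A"))
        with pytest.raises(ValueError, match="comparable"):
            ac.p_distance_matrix(msa)

    def test_k2p_exceeds_p_distance(self):
        dm_p = ac.p_distance_matrix(["AAAAAAAAAA", "AAAAAAAAGG"], model="p")
        dm_k = ac.p_distance_matrix(["AAAAAAAAAA", "AAAAAAAAGG"], model="k2p")
        assert dm_k.matrix[0, 1] > dm_p.matrix[0, 1]


class TestNeighborJoining:
    def test_four_taxa_exact_recovery_by_hand(self):
        # true tree ((A:1,B:2):1,(C:3,D:1)) => additive distances below
        labels = ("A", "B", "C", "D")
        m = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        tree = ac.nj_tree(ac.DistanceMatrix(labels, m))
        splits = tree.splits()
        fs = frozenset
        assert splits[fs({"C", "D"})] == pytest.approx(1.0)  # AB|CD internal edge
        assert splits[fs({"B"})] == pytest.approx(2.0)
        assert splits[fs({"C"})] == pytest.approx(3.0)
        assert splits[fs({"D"})] == pytest.approx(1.0)
        assert splits[fs({"B", "C", "D"})] == pytest.approx(1.0)  # A's pendant edge
        assert tree.n_edges() == 5

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = ac.nj_tree(ac.DistanceMatrix(("A", "B", "C"), m))
        s = tree.splits()
        assert s[frozenset({"B"})] == pytest.approx(0.5 * (3 + 5 - 4))
        assert s[frozenset({"C"})] == pytest.approx(0.5 * (4 + 5 - 3))
        assert s[frozenset({"B", "C"})] == pytest.approx(0.5 * (3 + 4 - 5))

    def test_equidistant_matrix_yields_valid_tree(self):
        m = np.full((4, 4), 0.5)
        np.fill_diagonal(m, 0.0)
        tree = ac.nj_tree(ac.DistanceMatrix(("A", "B", "C", "D"), m))
        assert tree.n_edges() == 5
        assert set().union(*tree.splits().keys()) <= {"A", "B", "C", "D"}
        # degenerate ties resolve to the lowest-index join: A with B
        assert frozenset({"C", "D"}) in tree.splits()

    def test_recovers_random_additive_trees_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            labels, m, true_splits = random_additive_tree(rng, n)
            tree = ac.nj_tree(ac.DistanceMatrix(tuple(labels), m))
            got = tree.splits()
            assert set(got) == set(true_splits)
            for k in true_splits:
                assert got[k] == pytest.approx(true_splits[k], abs=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        labels, m, _ = random_additive_tree(rng, 6)
        mine = ac.nj_tree(ac.DistanceMatrix(tuple(labels), m))
        sk = nj(SkDM(m, labels))
        ref = min(labels)
        sk_splits = set()
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            key = side if ref not in side else frozenset(labels) - side
            if 1 < len(key) < len(labels) - 1:
                sk_splits.add(key)
        my_internal = {k for k in mine.splits() if 1 < len(k) < len(labels) - 1}
        assert my_internal == sk_splits

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ac.nj_tree(ac.DistanceMatrix(("A", "B"), np.zeros((2, 2))))
        with pytest.raises(ValueError):
            ac.DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestAssignSubfamily:
    def test_identical_to_library_entry(self, alu_library):
        name = sorted(alu_library)[0]
        got, dist, tree = ac.assign_subfamily(alu_library[name], alu_library)
        assert got == name and dist == 0.0
        assert tree is not None and "candidate" in tree.newick()

    def test_mutated_copy_assigned_to_source(self, alu_library, rng):
        from pprealu.synthetic_data import _mutate

        for name in alu_library:
            copy = _mutate(alu_library[name], 0.05, rng)
            assert ac.assign_subfamily(copy, alu_library)[0] == name

    def test_singleton_library(self):
        got, dist, tree = ac.assign_subfamily("ACGTACGT", {"only": "ACGTAGGT"})
        assert got == "only" and tree is None
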