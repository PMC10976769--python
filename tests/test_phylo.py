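import random

import numpy as np
import pytest

from _oracles import random_additive_distances
from conftest import random_rna
from mirfam.alignment import MsAlignment
from mirfam.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    neighbor_joining,
    p_distance,
)


class TestPDistance:
    def _aln(self, rows):
        return MsAlignment(rows=rows)

    def test_identical_rows_give_zero(self):
        aln = self._aln([("a", "ACGUACGU"), ("b", "ACGUACGU"), ("c", "ACGUACGU")])
        assert np.all(p_distance(aln).d == 0)

    def test_three_mismatches_over_21_sites(self):
        a = "ACGUACGUACGUACGUACGUA"
        b = "UCGUACGAACGUACGUACGUC"  # differs at positions 1, 8, 21
        aln = self._aln([("a", a), ("b", b), ("c", a)])
        d = p_distance(aln)
        assert d.d[0, 1] == pytest.approx(3 / 21, abs=1e-9)

    def test_pairwise_deletion_matches_hand_recount(self, rng):
        rows = []
        for i in range(4):
            seq = list(random_rna(rng, 40))
            for j in rng.sample(range(40), 6):
                seq[j] = "-"
            rows.append((f"r{i}", "".join(seq)))
        aln = self._aln(rows)
        d = p_distance(aln)
        for i in range(4):
            for j in range(4):
                cols = [
                    (rows[i][1][k], rows[j][1][k])
                    for k in range(40)
                    if "-" not in (rows[i][1][k], rows[j][1][k])
                ]
                expected = sum(x != y for x, y in cols) / len(cols)
                assert d.d[i, j] == pytest.approx(expected)

    def test_incomparable_pair_is_an_error_naming_the_pair(self):
        aln = self._aln([("a", "AC--"), ("b", "--GU"), ("c", "ACGU")])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            p_distance(aln)

    def test_jukes_cantor_correction_exceeds_p_distance(self):
        a = "ACGUACGUACGUACGUACGU"
        b = "ACGUACGAACGUACGUACGU"
        aln = self._aln([("a", a), ("b", b), ("c", a)])
        p = p_distance(aln).d[0, 1]
        jc = p_distance(aln, model="jukes-cantor").d[0, 1]
        assert jc > p


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 4.0], [2, 0, 4], [4, 4, 0]])
        tree = neighbor_joining(DistanceMatrix(taxa=["A", "B", "C"], d=d))
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive_matrix_recovers_split_and_internal_branch(self):
        # tree ((A:1,B:2):1,(C:2,D:3)): internal branch 1
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 4, 5.0],
                [3, 0, 5, 6],
                [4, 5, 0, 5],
                [5, 6, 5, 0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert np.allclose(tree.leaf_distances().d, d, atol=1e-12)
        internal = [
            n for n in tree.root.postorder()
            if n.children and n is not tree.root
        ]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(1.0)

    def test_additive_battery_reconstructs_path_lengths_exactly(self, rng):
        for _ in range(25):
            n = rng.randint(4, 12)
            taxa, d = random_additive_distances(n, rng)
            tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
            rec = tree.leaf_distances()
            assert rec.taxa == sorted(taxa)
            order = [taxa.index(t) for t in rec.taxa]
            assert np.max(np.abs(rec.d - d[np.ix_(order, order)])) < 1e-9

    def test_leaf_set_and_edge_count(self, rng):
        taxa, d = random_additive_distances(8, rng)
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
        assert tree.taxa == sorted(taxa)
        assert tree.n_edges() == 2 * 8 - 3

    def test_equidistant_taxa_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        trees = [
            neighbor_joining(DistanceMatrix(taxa=list("ABCD"), d=d.copy()))
            for _ in range(3)
        ]
        bps = [t.bipartitions() for t in trees]
        assert bps[0] == bps[1] == bps[2]
        # lowest index pair joined first: A and B end up together
        assert bps[0] == {frozenset({"C", "D"})}

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2.0], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(taxa=["a", "b", "c"], d=d)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2))))


def _signal_alignment(n_cols=40, signal_cols=10):
    """A/B share one state, C/D another at `signal_cols` fixed columns;
    remaining columns are constant (uninformative)."""
    base = ["A"] * n_cols
    rows = {}
    for name in "ABCD":
        row = base[:]
        for k in range(signal_cols):
            row[k] = "G" if name in "AB" else "U"
        # private mutations so no two rows are identical
        row[n_cols - 1 - "ABCD".index(name)] = "C"
        rows[name] = "".join(row)
    return MsAlignment(rows=sorted(rows.items()))


class TestBootstrap:
    def test_fully_supported_clade_reaches_high_support(self):
        aln = _signal_alignment()
        tree = bootstrap_supports(aln, replicates=100, seed=5)
        supports = [
            n.support for n in tree.root.postorder()
            if n.children and n is not tree.root
        ]
        assert supports and min(supports) >= 95.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        aln = _signal_alignment()
        tree = bootstrap_supports(aln, replicates=1, seed=3)
        for n in tree.root.postorder():
            if n.children and n is not tree.root and n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_supports_within_range_and_seed_stable(self):
        aln = _signal_alignment(signal_cols=3)
        t1 = bootstrap_supports(aln, replicates=50, seed=9)
        t2 = bootstrap_supports(aln, replicates=50, seed=9)
        s1 = sorted(n.support for n in t1.root.postorder() if n.support is not None)
        s2 = sorted(n.support for n in t2.root.postorder() if n.support is not None)
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        aln = _signal_alignment(signal_cols=6)
        t1 = bootstrap_supports(aln, replicates=200, seed=1)
        t2 = bootstrap_supports(aln, replicates=200, seed=2)
        s1 = {frozenset(n.leaf_labels()): n.support
              for n in t1.root.postorder() if n.support is not None}
        s2 = {frozenset(n.leaf_labels()): n.support
              for n in t2.root.postorder() if n.support is not None}
        for key in s1:
            if key in s2:
                assert abs(s1[key] - s2[key]) < 10.0

    def test_alignment_with_one_column_rejected(self):
        aln = MsAlignment(rows=[("a", "A"), ("b", "C"), ("c", "G")])
        with pytest.raises(ValueError, match="2 columns"):
            bootstrap_supports(aln, replicates=10, seed=0)
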