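"""Neighbor joining, bootstrap support, newick round-trips."""

import numpy as np
import pytest

from _oracles import random_additive_matrix, true_bipartitions
from satdna.consensus import msa_from_rows
from satdna.phylo import (DistanceMatrix, Tree, bootstrap_support,
                          group_support, neighbor_joining,
                          p_distance_matrix)


def branch_lengths(tree: Tree) -> dict[str, float]:
    return {l.name: l.length for l in tree.root.leaves()}


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = msa_from_rows(list("abc"), ["ACGT"] * 3)
        dm = p_distance_matrix(msa)
        assert (dm.matrix == 0).all()

    def test_hand_counted(self):
        msa = msa_from_rows(list("abc"), ["AAAA", "AAAT", "AATT"])
        dm = p_distance_matrix(msa)
        assert dm.matrix[0, 1] == 0.25
        assert dm.matrix[0, 2] == 0.5
        assert dm.matrix[1, 2] == 0.25

    def test_gap_columns_excluded_pairwise(self):
        msa = msa_from_rows(list("abc"), ["AC-T", "ACGT", "ACGA"])
        dm = p_distance_matrix(msa)
        assert dm.matrix[0, 1] == 0.0  # 3 comparable columns, all equal

    def test_incomparable_pair_rejected_by_name(self):
        msa = msa_from_rows(list("abc"), ["A--", "-C-", "ACG"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            p_distance_matrix(msa)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(8)]
        dm = p_distance_matrix(msa_from_rows([str(i) for i in range(8)],
                                             rows))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert (dm.matrix <= 1).all() and (dm.matrix >= 0).all()
        assert np.allclose(np.diag(dm.matrix), 0)


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # generating tree ((A:1,B:2):1,(C:3,D:1))
        ids = list("ABCD")
        m = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(ids, m))
        assert set(map(frozenset, t.bipartitions())) == {frozenset("CD")}
        assert branch_lengths(t) == {"A": 1, "B": 2, "C": 3, "D": 1}

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(list("XYZ"), m))
        assert branch_lengths(t) == {"X": 0.5, "Y": 1.5, "Z": 2.5}

    def test_equidistant_star_zero_internal_branches(self):
        m = np.full((5, 5), 0.5)
        np.fill_diagonal(m, 0.0)
        t = neighbor_joining(DistanceMatrix(list("ABCDE"), m))
        for bp, node in t.bipartitions().items():
            assert node.length == pytest.approx(0.0)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees_exactly(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        ids, m, edges = random_additive_matrix(n_taxa, rng)
        t = neighbor_joining(DistanceMatrix(ids, m))
        assert set(t.bipartitions()) == true_bipartitions(n_taxa, edges)
        # additive matrix: leaf branch length equals the pendant edge length
        pendant = {}
        for e, l in edges.items():
            u, v = tuple(e)
            leaf = u if u < n_taxa else v if v < n_taxa else None
            if leaf is not None:
                pendant[f"t{leaf}"] = l
        got = branch_lengths(t)
        for leaf, l in pendant.items():
            assert got[leaf] == pytest.approx(l)

    def test_matches_scikit_bio_topology(self):
        import skbio

        rng = np.random.default_rng(3)
        for _ in range(5):
            ids, m, _ = random_additive_matrix(6, rng)
            mine = neighbor_joining(DistanceMatrix(ids, m))
            ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids))
            ref_bps = set()
            all_leaves = frozenset(ids)
            for node in ref.non_tips():
                s = frozenset(t.name for t in node.tips())
                if 2 <= len(s) <= len(ids) - 2:
                    ref_bps.add(s if "t0" not in s else all_leaves - s)
            assert set(mine.bipartitions()) == ref_bps

    def test_binary_tree_has_n_minus_3_internal_edges(self):
        rng = np.random.default_rng(4)
        for n in (4, 5, 7, 9):
            ids, m, _ = random_additive_matrix(n, rng)
            t = neighbor_joining(DistanceMatrix(ids, m))
            assert len(t.bipartitions()) == n - 3


CLADE_ROWS = ["AAAAAAAAAAGGGGG", "AAAAAAAAAAGGGGC", "AAAAAAAAATGGGGG",
              "TTTTTTTTTTGGGGG", "TTTTTTTTTTGGGGC", "TTTTTTTTTCGGGGG"]
CLADE_IDS = [f"t{i}" for i in range(6)]


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self):
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = bootstrap_support(msa, n_replicates=1, seed=0)
        sups = {n.support for n in t.bipartitions().values()}
        assert sups <= {0.0, 100.0}

    def test_same_seed_same_supports(self):
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t1 = bootstrap_support(msa, n_replicates=50, seed=5)
        t2 = bootstrap_support(msa, n_replicates=50, seed=5)
        s1 = {bp: n.support for bp, n in t1.bipartitions().items()}
        s2 = {bp: n.support for bp, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_separated_clades_strongly_supported(self):
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = bootstrap_support(msa, n_replicates=100, seed=1)
        split = frozenset(["t3", "t4", "t5"])
        bps = t.bipartitions()
        assert split in bps
        assert bps[split].support >= 99.0

    def test_invariant_under_taxon_reordering(self):
        msa1 = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        perm = [3, 0, 5, 2, 4, 1]
        msa2 = msa_from_rows([CLADE_IDS[i] for i in perm],
                             [CLADE_ROWS[i] for i in perm])
        s1 = {bp: n.support for bp, n
              in bootstrap_support(msa1, 50, seed=7).bipartitions().items()}
        s2 = {bp: n.support for bp, n
              in bootstrap_support(msa2, 50, seed=7).bipartitions().items()}
        assert s1 == s2


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = bootstrap_support(msa, n_replicates=20, seed=2)
        back = Tree.from_newick(t.to_newick())
        assert sorted(back.leaf_names()) == sorted(t.leaf_names())
        bp1, bp2 = t.bipartitions(), back.bipartitions()
        assert bp1.keys() == bp2.keys()
        for bp in bp1:
            assert bp2[bp].length == pytest.approx(bp1[bp].length,
                                                   abs=1e-9)
            assert bp2[bp].support == pytest.approx(bp1[bp].support)


class TestGroupSupport:
    def test_planted_families_supported(self):
        labels = {f"t{i}": ("x" if i < 3 else "y") for i in range(6)}
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = bootstrap_support(msa, n_replicates=100, seed=3)
        verdicts = group_support(t, labels)
        assert verdicts == {"x": "supported", "y": "supported"}

    def test_scattered_label_not_supported(self):
        labels = {"t0": "x", "t3": "x", "t1": "y", "t2": "y",
                  "t4": "y", "t5": "y"}
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = bootstrap_support(msa, n_replicates=50, seed=4)
        assert group_support(t, labels)["x"] == "not supported"

    def test_whole_set_and_singleton_not_assessable(self):
        msa = msa_from_rows(CLADE_IDS, CLADE_ROWS)
        t = neighbor_joining(p_distance_matrix(msa))
        all_one = group_support(t, {i: "z" for i in CLADE_IDS})
        assert all_one["z"] == "not assessable"
        single = group_support(t, {"t0": "s"})
        assert single["s"] == "not assessable"
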