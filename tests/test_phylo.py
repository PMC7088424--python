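"""Alignment distances, neighbor joining, bootstrap support."""

import random

import pytest

from acepamir.phylo import (
    DistanceMatrix,
    align_global,
    bootstrap_support,
    center_star_msa,
    nj_tree,
    pairwise_distance,
)

from _oracles import random_additive_case


def _random_rna(rng, n):
    return "".join(rng.choice("AUGC") for _ in range(n))


class TestDistances:
    def test_identical_sequences(self):
        assert pairwise_distance("AUGCAUGC", "AUGCAUGC") == 0.0

    def test_fully_different(self):
        assert pairwise_distance("AAAA", "UUUU") == 1.0

    def test_alignment_score_matches_biopython(self, rng):
        """Gotoh optimal scores agree with an independent aligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        for _ in range(20):
            a = _random_rna(rng, rng.randint(10, 60))
            b = _random_rna(rng, rng.randint(10, 60))
            _, _, score = align_global(a, b)
            assert score == pytest.approx(aligner.score(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("", "AUGC")

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], [[0.0, 1.0], [2.0, 0.0]])


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):5,C:3,D:4) -> path-length matrix
        labels = ["A", "B", "C", "D"]
        d = [
            [0.0, 3.0, 9.0, 10.0],
            [3.0, 0.0, 10.0, 11.0],
            [9.0, 10.0, 0.0, 7.0],
            [10.0, 11.0, 7.0, 0.0],
        ]
        tree = nj_tree(DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lengths = {}

        def walk(node):
            for c in node.children:
                if c.is_leaf():
                    lengths[c.label] = c.length
                walk(c)

        walk(tree.root)
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        d = [[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]
        tree = nj_tree(DistanceMatrix(labels, d))
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["x"], [[0.0]]))

    def test_two_taxa_single_edge(self):
        tree = nj_tree(DistanceMatrix(["x", "y"], [[0.0, 4.0], [4.0, 0.0]]))
        assert {c.label for c in tree.root.children} == {"x", "y"}
        assert all(c.length == 2.0 for c in tree.root.children)

    def test_random_additive_eight_taxon_trees_recovered(self):
        """NJ is consistent: additive matrices give back the generating topology."""
        for seed in range(50):
            labels, matrix, true_bips = random_additive_case(8, seed)
            tree = nj_tree(DistanceMatrix(labels, matrix))
            assert tree.bipartitions() == true_bips, f"seed {seed}"

    def test_taxon_order_invariance(self):
        labels, matrix, _ = random_additive_case(7, 123)
        tree1 = nj_tree(DistanceMatrix(labels, matrix))
        order = list(range(len(labels)))[::-1]
        labels2 = [labels[i] for i in order]
        matrix2 = [[matrix[i][j] for j in order] for i in order]
        tree2 = nj_tree(DistanceMatrix(labels2, matrix2))
        assert tree1.bipartitions() == tree2.bipartitions()

    def test_agrees_with_skbio_on_additive_matrix(self):
        """Independent NJ implementation recovers the same topology."""
        import numpy as np
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        labels, matrix, true_bips = random_additive_case(6, 77)
        sk_tree = sk_nj(SkDM(np.array(matrix), labels))
        sk_bips = set()
        n = len(labels)
        for node in sk_tree.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                other = frozenset(labels) - tips
                sk_bips.add(min(tips, other, key=lambda s: (len(s), sorted(s))))
        ours = nj_tree(DistanceMatrix(labels, matrix)).bipartitions()
        assert ours == true_bips
        assert sk_bips <= ours  # rooted traversal may hide one split at the root


class TestBootstrap:
    def _clade_sequences(self, seed=7, n=60):
        rng = random.Random(seed)
        base = _random_rna(rng, n)

        def mutate(s, k, sd):
            r = random.Random(sd)
            s = list(s)
            for _ in range(k):
                p = r.randrange(len(s))
                s[p] = r.choice("AUGC")
            return "".join(s)

        far = mutate(base, 30, 3)
        return {
            "a1": mutate(base, 2, 1),
            "a2": mutate(base, 2, 2),
            "b1": far,
            "b2": mutate(far, 2, 4),
            "out": mutate(base, 45, 5),
        }

    def test_unanimous_columns_give_full_support(self):
        seqs = self._clade_sequences()
        tree = bootstrap_support(seqs, n_replicates=100, seed=9)
        supports = []

        def walk(node):
            for c in node.children:
                if c.support is not None:
                    supports.append(c.support)
                walk(c)

        walk(tree.root)
        assert supports, "no internal supports assigned"
        assert all(0 <= s <= 100 for s in supports)
        assert max(supports) >= 95  # the deep a/b split is unambiguous

    def test_same_seed_same_supports(self):
        seqs = self._clade_sequences()
        t1 = bootstrap_support(seqs, n_replicates=50, seed=11)
        t2 = bootstrap_support(seqs, n_replicates=50, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_small_replicates_near_large_reference(self):
        """100-replicate supports sit within sampling error of a 2000-replicate run."""
        seqs = self._clade_sequences(seed=21)

        def support_map(tree):
            out = {}

            def walk(node, leaves_all):
                below = set()
                for c in node.children:
                    below |= walk(c, leaves_all)
                if node.support is not None:
                    key = frozenset(below)
                    out[key] = node.support
                return below or {node.label}

            walk(tree.root, set())
            return out

        small = support_map(bootstrap_support(seqs, n_replicates=100, seed=1))
        large = support_map(bootstrap_support(seqs, n_replicates=2000, seed=2))
        for key, s in small.items():
            if key in large:
                # 4 sigma of a binomial proportion at n=100
                assert abs(s - large[key]) <= 20

    def test_msa_rows_equal_length(self):
        seqs = self._clade_sequences()
        rows = center_star_msa(seqs)
        lengths = {len(v) for v in rows.values()}
        assert len(lengths) == 1
        for lab, seq in seqs.items():
            assert rows[lab].replace("-", "") == seq
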