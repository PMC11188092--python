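"""Neighbor joining, rooting, ultrametrization and subtree decomposition."""

import numpy as np
import pytest

from polswap.genome_distance import DistanceMatrix
from polswap.synthetic_data import sample_tree
from polswap.tree import (
    constrained_nj,
    cut_subtrees,
    midpoint_root,
    nj_tree,
    ultrametrize,
)
from tests.conftest import leaf_distance_matrix, random_metric_tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5.0, 9.0], [5.0, 0, 10.0], [9.0, 10.0, 0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        # the realized tree metric must equal the closed-form pendant
        # branches a=(d_ab+d_ac-d_bc)/2=2, b=3, c=7 exactly
        got = leaf_distance_matrix(tree)
        assert np.allclose(got.d, d, atol=1e-12)

    def test_two_taxa_single_edge(self):
        tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 3.0], [3.0, 0]])))
        d = leaf_distance_matrix(tree)
        assert d.d[0, 1] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovered_exactly(self, seed):
        source = random_metric_tree(8, seed)
        dm = leaf_distance_matrix(source)
        tree = nj_tree(dm)
        assert tree.bipartitions() == source.bipartitions()
        assert np.allclose(leaf_distance_matrix(tree).d, dm.d, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1.1, 0, 2], [2, 2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(DistanceMatrix(list("abc"), d))

    def test_nan_rejected(self):
        d = np.array([[0, np.nan, 2], [np.nan, 0, 2], [2, 2, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(DistanceMatrix(list("abc"), d))


class TestMidpointRoot:
    def test_two_leaves_split_at_half(self):
        tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))
        rooted = midpoint_root(tree)
        assert [l.length for l in rooted.leaves()] == [0.5, 0.5]

    @pytest.mark.parametrize("seed", range(8))
    def test_root_balances_max_depths(self, seed):
        tree = midpoint_root(random_metric_tree(7, 50 + seed))
        assert len(tree.root.children) == 2
        sides = []
        for child in tree.root.children:
            sub = tree.copy()  # depths via full traversal below each child
            depths = []
            stack = [(child, child.length)]
            while stack:
                node, d = stack.pop()
                if node.is_leaf:
                    depths.append(d)
                for c in node.children:
                    stack.append((c, d + c.length))
            sides.append(max(depths))
        assert sides[0] == pytest.approx(sides[1], rel=1e-9)


class TestUltrametrize:
    def test_already_ultrametric_unchanged(self):
        tree = sample_tree(8, 0.3, 5)
        before = tree.to_newick(precision=12)
        after = ultrametrize(tree)
        d0 = leaf_distance_matrix(tree)
        d1 = leaf_distance_matrix(after)
        assert np.allclose(d0.d, d1.d, atol=1e-12)

    def test_cherry_branches_balanced_to_mean(self):
        from polswap.formats_io import read_newick

        tree = read_newick("(a:1,b:3);")
        out = ultrametrize(tree)
        assert {l.length for l in out.leaves()} == {2.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_ultrametricity_and_mean_depth(self, seed):
        tree = random_metric_tree(9, 200 + seed)
        mean_depth = float(np.mean(list(tree.leaf_depths().values())))
        out = ultrametrize(tree)
        depths = list(out.leaf_depths().values())
        assert max(depths) - min(depths) <= 1e-9
        assert depths[0] == pytest.approx(mean_depth, rel=1e-12)
        assert out.bipartitions() == tree.bipartitions()


def brute_force_cut(tree, depth):
    """Oracle: classify every node by (height, parent height)."""
    heights = {}
    for node in tree.postorder():
        heights[node] = 0.0 if node.is_leaf else max(
            c.length + heights[c] for c in node.children
        )
    roots = [
        n for n in tree.preorder()
        if heights[n] <= depth and (n.parent is None or heights[n.parent] > depth)
    ]
    out = []
    for r in roots:
        stack, leaves = [r], set()
        while stack:
            n = stack.pop()
            if n.is_leaf:
                leaves.add(n.name)
            stack.extend(n.children)
        out.append(frozenset(leaves))
    return set(out)


class TestCutSubtrees:
    def test_shallow_tree_single_subtree(self):
        tree = sample_tree(6, 0.10, 3)
        decomp = cut_subtrees(tree, 0.15)
        assert len(decomp.subtrees) == 1
        assert decomp.subtrees[0].leaf_ids == frozenset(tree.leaf_names())

    def test_depth_zero_singletons(self):
        tree = sample_tree(6, 0.3, 4)
        decomp = cut_subtrees(tree, 0.0)
        assert sorted(len(s.leaf_ids) for s in decomp.subtrees) == [1] * 6

    def test_non_ultrametric_rejected(self):
        tree = random_metric_tree(5, 77)
        with pytest.raises(ValueError, match="ultrametric"):
            cut_subtrees(tree, 0.15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_classifier(self, seed):
        rng = np.random.default_rng(300 + seed)
        tree = sample_tree(10, float(rng.uniform(0.1, 0.5)), rng)
        depth = float(rng.uniform(0.0, 0.4))
        decomp = cut_subtrees(tree, depth)
        got = {s.leaf_ids for s in decomp.subtrees}
        assert got == brute_force_cut(tree, depth)
        # partition property
        union = set()
        for s in decomp.subtrees:
            assert not (union & s.leaf_ids)
            union |= s.leaf_ids
        assert union == set(tree.leaf_names())


class TestConstrainedNJ:
    def test_single_group_equals_plain_nj(self):
        source = random_metric_tree(6, 11)
        dm = leaf_distance_matrix(source)
        a = nj_tree(dm).to_newick()
        b = constrained_nj(dm, [list(dm.ids)]).to_newick()
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_true_clades_recover_unconstrained_topology(self, seed):
        source = random_metric_tree(8, 400 + seed)
        dm = leaf_distance_matrix(source)
        # use one true clade of the source tree as the constraint
        split = sorted(source.bipartitions(), key=lambda s: (-len(s), sorted(s)))[0]
        groups = [sorted(split), sorted(set(dm.ids) - set(split))]
        tree = constrained_nj(dm, groups)
        assert tree.bipartitions() == source.bipartitions()

    def test_conflicting_groups_still_monophyletic(self):
        source = random_metric_tree(8, 17)
        dm = leaf_distance_matrix(source)
        ids = list(dm.ids)
        groups = [ids[::2], ids[1::2]]  # interleaved: conflicts with source
        tree = constrained_nj(dm, groups)
        for g in groups:
            gset = frozenset(g)
            sides = tree.bipartitions()
            assert gset in sides or (frozenset(ids) - gset) in sides

    def test_empty_group_rejected(self):
        dm = leaf_distance_matrix(random_metric_tree(4, 1))
        with pytest.raises(ValueError, match="empty"):
            constrained_nj(dm, [list(dm.ids), []])
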