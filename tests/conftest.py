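"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from polswap.genome_distance import DistanceMatrix
from polswap.synthetic_data import SimConfig, sample_tree, simulate_clade
from polswap.tree import PhyloTree


def random_metric_tree(n_leaves: int, seed: int) -> PhyloTree:
    """A random tree with positive, non-ultrametric branch lengths."""
    rng = np.random.default_rng(seed)
    tree = sample_tree(n_leaves, 1.0, rng)
    for node in tree.preorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.05, 1.0))
    return tree


def leaf_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise leaf path lengths, computed independently of the package's
    tree metrics (explicit root paths + lowest common ancestor)."""
    paths = {}
    for leaf in tree.leaves():
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent
        paths[leaf.name] = path
    depth = {}

    def fill(node, d):
        depth[node] = d
        for c in node.children:
            fill(c, d + c.length)

    fill(tree.root, 0.0)
    names = sorted(paths)
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi = paths[names[i]]
        pj_set = set(paths[names[j]])
        lca = next(nd for nd in pi if nd in pj_set)
        dist = depth[paths[names[i]][0]] + depth[paths[names[j]][0]] - 2 * depth[lca]
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(names, d)


@pytest.fixture(scope="session")
def small_clade():
    """One modest simulated clade with a planted swap, reused read-only."""
    return simulate_clade(
        SimConfig(seed=11, n_genomes=8, n_genes=24, n_swap_events=1)
    )
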