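"""Rooted phylogenetic trees: neighbor joining, midpoint rooting,
ultrametrization, depth-threshold subtree decomposition, and constrained
tree construction.

Node heights are measured from the leaves upward: in an ultrametric tree
every leaf sits at height 0 and every internal node's height is its (common)
path length to any descendant leaf.  The genome tree is cut at a fixed height
(default 0.15, roughly a genus level) to obtain the subtree units within
which DNAP heterogeneity is assessed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "PhyloTree",
    "SubtreeDecomposition",
    "nj_tree",
    "midpoint_root",
    "ultrametrize",
    "cut_subtrees",
    "constrained_nj",
]


class TreeNode:
    """A node in a rooted tree. ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent", "height")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.height: Optional[float] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or '?'} {kind} len={self.length:g}>"


class PhyloTree:
    """A rooted, branch-lengthed tree over named leaves."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- basic metrics -----------------------------------------------------

    def leaf_depths(self) -> dict[str, float]:
        """Path length from the root to every leaf."""
        depths: dict[str, float] = {}
        stack = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                depths[node.name] = d
            for c in node.children:
                stack.append((c, d + c.length))
        return depths

    def node_heights(self) -> dict[TreeNode, float]:
        """Max distance from each node down to its descendant leaves."""
        heights: dict[TreeNode, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                heights[node] = 0.0
            else:
                heights[node] = max(c.length + heights[c] for c in node.children)
        return heights

    def is_ultrametric(self, rel_tol: float = 1e-9, abs_tol: float = 1e-12) -> bool:
        depths = list(self.leaf_depths().values())
        spread = max(depths) - min(depths)
        scale = max(max(depths), abs_tol)
        return spread <= max(rel_tol * scale, abs_tol)

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            new.height = node.height
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})" + (node.name or "")
            if node.parent is None:
                return label
            return f"{label}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    # -- topology utilities ------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each as the smaller-or-canonical side."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = frozenset(n.name for n in _subtree_iter(node) if n.is_leaf)
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: sorted(s)))
        return splits

    def restrict(self, keep: Sequence[str]) -> "PhyloTree":
        """Prune to the given leaf set, suppressing unifurcations and
        summing branch lengths through removed degree-2 nodes."""
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_names())
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")

        def prune(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.name in keep_set:
                    new = TreeNode(node.name, node.length)
                    return new
                return None
            kids = [prune(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            new = TreeNode(node.name, node.length)
            for k in kids:
                new.add_child(k)
            return new

        root = prune(self.root)
        if root is None:
            raise ValueError("empty restriction")
        root.length = 0.0
        return PhyloTree(root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.leaf_names())} leaves>"


def _subtree_iter(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm) -> PhyloTree:
    """Saitou–Nei neighbor joining on a :class:`DistanceMatrix`.

    Negative branch-length estimates are clamped to zero; ties in the Q
    criterion are broken by the lowest (i, j) index pair in the current
    working matrix.  The unrooted result is returned rooted at the last
    join, with the final edge split at its midpoint.
    """
    ids = list(dm.ids)
    d = np.asarray(dm.d, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name) for name in ids]
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = d[0, 1] / 2.0
            root.add_child(node)
        return PhyloTree(root)

    active = list(range(n))
    work = d.copy()
    while len(active) > 2:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        q = (q + q.T) / 2.0  # guard against floating asymmetry
        iu = np.triu_indices(m, 1)
        vals = q[iu]
        # lowest (i, j) among exact ties (triu order is lexicographic)
        first = int(np.argmax(vals == vals.min()))
        i_loc, j_loc = int(iu[0][first]), int(iu[1][first])
        gi, gj = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode()
        nodes[gi].length = li
        nodes[gj].length = lj
        new.add_child(nodes[gi])
        new.add_child(nodes[gj])
        # distances from the new node to the remaining taxa
        for k_loc, gk in enumerate(active):
            if k_loc in (i_loc, j_loc):
                continue
            dk = (sub[i_loc, k_loc] + sub[j_loc, k_loc] - dij) / 2.0
            work[gi, gk] = work[gk, gi] = dk
        nodes[gi] = new
        active.pop(j_loc)

    gi, gj = active
    dij = work[gi, gj]
    root = TreeNode()
    nodes[gi].length = dij / 2.0
    nodes[gj].length = dij / 2.0
    root.add_child(nodes[gi])
    root.add_child(nodes[gj])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Midpoint rooting


def _reroot_on_edge(tree: PhyloTree, child: TreeNode, dist_from_child: float) -> PhyloTree:
    """Place a new root on the branch above ``child`` at the given distance."""
    old_len = child.length
    parent = child.parent
    if parent is None:
        raise ValueError("cannot reroot on the root's (absent) parent edge")
    parent.children.remove(child)

    new_root = TreeNode()
    child.length = dist_from_child
    new_root.add_child(child)

    # re-hang the former parent side, flipping parent links up to the old root
    prev = new_root
    node = parent
    blen = old_len - dist_from_child
    while node is not None:
        next_parent = node.parent
        next_len = node.length
        if next_parent is not None:
            next_parent.children.remove(node)
        node.parent = None
        node.length = max(blen, 0.0)
        prev.add_child(node)
        prev = node
        node = next_parent
        blen = next_len

    _suppress_unifurcations(new_root)
    return PhyloTree(new_root)


def _suppress_unifurcations(root: TreeNode) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for c in list(node.children):
            while len(c.children) == 1 and not c.is_leaf:
                only = c.children[0]
                only.length += c.length
                only.parent = node
                node.children[node.children.index(c)] = only
                c = only
            stack.append(c)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest (sorted) leaf-name pair.
    """
    tree = tree.copy()
    leaves = {n.name: n for n in tree.leaves()}
    if len(leaves) == 1:
        return tree
    # pairwise leaf distances
    node_depth: dict[TreeNode, float] = {}
    stack = [(tree.root, 0.0)]
    while stack:
        node, dd = stack.pop()
        node_depth[node] = dd
        for c in node.children:
            stack.append((c, dd + c.length))
    paths: dict[str, list[TreeNode]] = {}
    for name, leaf in leaves.items():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        paths[name] = path

    best = None  # (-dist, (u, v))
    for u, v in itertools.combinations(sorted(leaves), 2):
        su = set(paths[u])
        lca = next(nd for nd in paths[v] if nd in su)
        dist = node_depth[leaves[u]] + node_depth[leaves[v]] - 2 * node_depth[lca]
        key = (-dist, (u, v))
        if best is None or key < best:
            best = key
    dist = -best[0]
    u, v = best[1]

    # walk from u toward v accumulating distance until the midpoint
    su = set(paths[u])
    lca = next(nd for nd in paths[v] if nd in su)
    up_path = paths[u][: paths[u].index(lca) + 1]            # u ... lca
    down_path = paths[v][: paths[v].index(lca)][::-1]        # just below lca ... v
    full = up_path + down_path                               # u ... lca ... v
    target = dist / 2.0
    cum = 0.0
    for a, b in zip(full, full[1:]):
        if b is a.parent:  # walking up: the edge belongs to child a
            edge_child, edge_len = a, a.length
            dist_from_child = target - cum
        else:  # walking down: the edge belongs to child b
            edge_child, edge_len = b, b.length
            dist_from_child = edge_len - (target - cum)
        if target <= cum + edge_len + 1e-15:
            x = min(max(dist_from_child, 0.0), edge_len)
            return _reroot_on_edge(tree, edge_child, x)
        cum += edge_len
    raise RuntimeError("midpoint not found on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Ultrametrization


def ultrametrize(tree: PhyloTree) -> PhyloTree:
    """Make a rooted tree exactly ultrametric by balancing subtrees in a
    single descent.

    For every node ``v`` let ``m(v)`` be the mean path length from ``v`` to
    its descendant leaves.  The root is assigned height ``m(root)``; each
    child ``c`` with original branch ``b`` is assigned height
    ``H(v) * m(c) / (b + m(c))`` (zero for leaves and when ``b + m(c) = 0``),
    and the new branch is ``H(v) - H(c)``.  Topology and leaf set are
    preserved; the output's total depth equals the mean original root-to-leaf
    depth.
    """
    tree = tree.copy()
    n_leaves: dict[TreeNode, int] = {}
    mean_h: dict[TreeNode, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            n_leaves[node] = 1
            mean_h[node] = 0.0
        else:
            tot = sum(n_leaves[c] * (c.length + mean_h[c]) for c in node.children)
            cnt = sum(n_leaves[c] for c in node.children)
            n_leaves[node] = cnt
            mean_h[node] = tot / cnt

    assigned: dict[TreeNode, float] = {tree.root: mean_h[tree.root]}
    for node in tree.preorder():
        hv = assigned[node]
        node.height = hv
        for c in node.children:
            if c.is_leaf:
                hc = 0.0
            else:
                denom = c.length + mean_h[c]
                hc = 0.0 if denom == 0 else hv * mean_h[c] / denom
            assigned[c] = hc
            c.length = hv - hc
    return tree


# ---------------------------------------------------------------------------
# Depth-threshold subtree decomposition


@dataclass
class Subtree:
    subtree_id: str
    root: TreeNode
    leaf_ids: frozenset[str]
    height: float


@dataclass
class SubtreeDecomposition:
    """Partition of an ultrametric tree's leaves into maximal subtrees of
    height at most ``depth_threshold``."""

    depth_threshold: float
    subtrees: list[Subtree]
    leaf_to_subtree: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.leaf_to_subtree:
            self.leaf_to_subtree = {
                leaf: st.subtree_id for st in self.subtrees for leaf in st.leaf_ids
            }


def cut_subtrees(tree: PhyloTree, depth: float = 0.15) -> SubtreeDecomposition:
    """Cut an ultrametric tree at a height threshold.

    Subtree roots are exactly the nodes of height <= ``depth`` whose parent
    (if any) has height > ``depth``; their leaf sets partition the leaves.
    """
    if not tree.is_ultrametric(rel_tol=1e-6):
        raise ValueError("cut_subtrees requires an ultrametric tree")
    heights: dict[TreeNode, float] = {}
    for node in tree.postorder():
        heights[node] = 0.0 if node.is_leaf else max(
            c.length + heights[c] for c in node.children
        )
    subtrees: list[Subtree] = []
    idx = 0
    for node in tree.preorder():
        h = heights[node]
        parent_h = heights[node.parent] if node.parent is not None else None
        if h <= depth and (parent_h is None or parent_h > depth):
            leaf_ids = frozenset(
                n.name for n in _subtree_iter(node) if n.is_leaf
            )
            subtrees.append(Subtree(f"st{idx:04d}", node, leaf_ids, h))
            idx += 1
    return SubtreeDecomposition(depth, subtrees)


# ---------------------------------------------------------------------------
# Constrained neighbor joining


def _reroot_at_node(tree: PhyloTree, target: TreeNode) -> PhyloTree:
    """Make an existing internal node the root by flipping parent links."""
    if target.parent is None:
        return tree
    prev = None
    node = target
    blen = 0.0
    while node is not None:
        next_parent = node.parent
        next_len = node.length
        if next_parent is not None:
            next_parent.children.remove(node)
        node.parent = None
        if prev is not None:
            node.length = blen
            prev.add_child(node)
        prev = node
        node = next_parent
        blen = next_len
    target.length = 0.0
    _suppress_unifurcations(target)
    return PhyloTree(target)


def constrained_nj(dm, groups: Sequence[Sequence[str]]) -> PhyloTree:
    """NJ under a monophyly constraint.

    Each group is resolved internally by NJ on its sub-matrix, rooted at its
    attachment point (located with a pseudo-outgroup at the mean distance to
    all non-group taxa); the group subtrees are then joined by NJ on the
    between-group mean distances.  Every group is monophyletic in the
    result, and on an additive matrix whose tree already satisfies the
    constraint the source tree is recovered exactly.
    """
    from .genome_distance import DistanceMatrix

    ids = list(dm.ids)
    index = {t: i for i, t in enumerate(ids)}
    groups = [list(g) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = [t for g in groups for t in g]
    if sorted(flat) != sorted(ids):
        raise ValueError("groups must partition the taxon set")

    d = np.asarray(dm.d, dtype=float)
    if len(groups) == 1:
        return nj_tree(dm)

    OUT = "\x00outgroup\x00"
    subtrees: list[TreeNode] = []
    mean_depths: list[float] = []
    for g in groups:
        if len(g) == 1:
            subtrees.append(TreeNode(g[0]))
            mean_depths.append(0.0)
            continue
        gidx = [index[t] for t in g]
        rest = [i for i in range(len(ids)) if i not in set(gidx)]
        sub = d[np.ix_(gidx, gidx)]
        # pseudo-outgroup row: mean distance to every non-group taxon
        out_row = d[np.ix_(gidx, rest)].mean(axis=1)
        aug = np.zeros((len(g) + 1, len(g) + 1))
        aug[: len(g), : len(g)] = sub
        aug[: len(g), -1] = out_row
        aug[-1, : len(g)] = out_row
        st = nj_tree(DistanceMatrix(g + [OUT], aug))
        out_leaf = next(n for n in st.leaves() if n.name == OUT)
        attach = out_leaf.parent
        attach.children.remove(out_leaf)
        rooted = _reroot_at_node(st, attach)
        root = rooted.root
        while len(root.children) == 1:  # degenerate attachment at a leaf edge
            root = root.children[0]
            root.parent = None
        rooted = PhyloTree(root)
        subtrees.append(rooted.root)
        depths = rooted.leaf_depths()
        mean_depths.append(sum(depths.values()) / len(depths))

    gd = np.zeros((len(groups), len(groups)))
    for i, gi in enumerate(groups):
        for j in range(i + 1, len(groups)):
            gj = groups[j]
            vals = [d[index[a], index[b]] for a in gi for b in gj]
            gd[i, j] = gd[j, i] = float(np.mean(vals))
    skeleton = nj_tree(DistanceMatrix([f"__group{i}__" for i in range(len(groups))], gd))

    # replace placeholder leaves with the group subtrees, discounting the
    # mean within-group depth absorbed into the group pendant edge
    for leaf in skeleton.leaves():
        gidx = int(leaf.name[7:-2])
        sub_root = subtrees[gidx]
        sub_root.length = max(leaf.length - mean_depths[gidx], 0.0)
        parent = leaf.parent
        if parent is None:
            return PhyloTree(sub_root)
        parent.children[parent.children.index(leaf)] = sub_root
        sub_root.parent = parent
    return skeleton
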