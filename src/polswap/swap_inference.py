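"""Detection of DNAP-heterogeneous subtrees and parsimony inference of swap
events.

Two heterogeneity types are distinguished within the depth-threshold
subtrees of the genome tree: type (i), "swap" — at least two genomes each
carrying a single DNAP, with at least two distinct families among them; and
type (ii), "co-occurrence" — at least one genome carrying two or more DNAPs
of different families.  Heterogeneous subtrees are grouped with their
DNAP-bearing sister subtrees into swap clades, and the minimal set of
replacement events explaining the leaf states on the clade tree is found by
Sankoff small parsimony over composite (family, clade) states.

Event direction is not asserted: unless a root state is supplied, events are
reported as state changes on edges under one (deterministically chosen)
minimum-change assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .dnap_annotation import GenomeDnapSummary
from .tree import PhyloTree, SubtreeDecomposition, TreeNode, _subtree_iter

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneousSubtree",
    "SwapClade",
    "SwapEvent",
    "SwapReport",
    "detect_heterogeneous_subtrees",
    "group_swap_clades",
    "infer_swap_events",
]

State = tuple[str, Optional[str]]  # (family, clade label)


@dataclass
class HeterogeneousSubtree:
    subtree_id: str
    genomes: frozenset[str]
    families: tuple[str, ...]
    type: str  # "swap" (i) or "co-occurrence" (ii)


@dataclass
class SwapClade:
    clade_id: str
    root: TreeNode
    subtree_ids: tuple[str, ...]
    genomes: frozenset[str]


@dataclass
class SwapEvent:
    child_id: str  # name/id of the child node of the edge
    from_state: State
    to_state: State
    kind: str  # "inter-family" | "intra-family"

    def __post_init__(self):
        assert self.from_state != self.to_state


@dataclass
class SwapReport:
    clade_id: str
    min_changes: float  # integer-valued under unit costs
    events: list[SwapEvent]
    node_states: dict[str, State] = field(default_factory=dict)


def detect_heterogeneous_subtrees(
    decomp: SubtreeDecomposition,
    summaries: dict[str, GenomeDnapSummary],
) -> list[HeterogeneousSubtree]:
    """Find subtrees with DNAPs of different families.

    Genomes absent from ``summaries`` are treated as no-DNAP (logged).
    Subtrees with fewer than two genomes never yield a type (i) record.
    """
    out: list[HeterogeneousSubtree] = []
    for st in decomp.subtrees:
        single_families: dict[str, str] = {}
        singles = 0
        for gid in sorted(st.leaf_ids):
            summ = summaries.get(gid)
            if summ is None:
                logger.info("genome %s has no DNAP summary; treated as no-DNAP", gid)
                continue
            if summ.status == "single-DNAP":
                singles += 1
                single_families[gid] = summ.families[0]
            elif summ.status == "multi-DNAP":
                out.append(
                    HeterogeneousSubtree(
                        st.subtree_id,
                        frozenset([gid]),
                        tuple(summ.families),
                        "co-occurrence",
                    )
                )
        fams = sorted(set(single_families.values()))
        if singles >= 2 and len(fams) >= 2:
            out.append(
                HeterogeneousSubtree(
                    st.subtree_id,
                    frozenset(single_families),
                    tuple(fams),
                    "swap",
                )
            )
    return out


def group_swap_clades(
    tree: PhyloTree,
    decomp: SubtreeDecomposition,
    het_subtrees: Sequence[HeterogeneousSubtree],
    summaries: dict[str, GenomeDnapSummary],
    max_clade_depth: float = 0.45,
) -> list[SwapClade]:
    """Group heterogeneous subtrees with DNAP-bearing sisters into clades.

    From each heterogeneous subtree root the tree is ascended while the
    parent's height does not exceed ``max_clade_depth`` and the parent's
    other children contain at least one DNAP-encoding genome; overlapping
    ascents are merged into maximal clades.
    """
    heights = tree.node_heights()
    st_by_id = {st.subtree_id: st for st in decomp.subtrees}
    dnap_bearing = {
        gid for gid, s in summaries.items() if s.status != "no-DNAP"
    }

    def leaves_under(node: TreeNode) -> set[str]:
        return {n.name for n in _subtree_iter(node) if n.is_leaf}

    endpoints: dict[str, TreeNode] = {}
    for het in het_subtrees:
        node = st_by_id[het.subtree_id].root
        while node.parent is not None:
            parent = node.parent
            if heights[parent] > max_clade_depth:
                break
            sibling_leaves = set()
            for child in parent.children:
                if child is not node:
                    sibling_leaves |= leaves_under(child)
            if not (sibling_leaves & dnap_bearing):
                break
            node = parent
        endpoints[het.subtree_id] = node

    # merge ascents whose endpoints are nested (one an ancestor of the other)
    def is_ancestor(a: TreeNode, b: TreeNode) -> bool:
        while b is not None:
            if b is a:
                return True
            b = b.parent
        return False

    groups: list[tuple[TreeNode, set[str]]] = []
    for st_id, node in sorted(endpoints.items()):
        placed = False
        for k, (root, members) in enumerate(groups):
            if is_ancestor(root, node):
                members.add(st_id)
                placed = True
                break
            if is_ancestor(node, root):
                groups[k] = (node, members | {st_id})
                placed = True
                break
        if not placed:
            groups.append((node, {st_id}))

    clades = []
    for k, (root, members) in enumerate(groups):
        clade_leaves = leaves_under(root)
        member_ids = tuple(
            st.subtree_id
            for st in decomp.subtrees
            if st.leaf_ids <= clade_leaves
        )
        clades.append(
            SwapClade(f"clade{k + 1}", root, member_ids, frozenset(clade_leaves))
        )
    return clades


# ---------------------------------------------------------------------------
# Sankoff small parsimony


def _unit_cost_factory(inter_cost: float, intra_cost: float) -> Callable[[State, State], float]:
    def cost(a: State, b: State) -> float:
        if a == b:
            return 0.0
        if a[0] == b[0]:
            return intra_cost
        return inter_cost

    return cost


def infer_swap_events(
    tree: PhyloTree,
    leaf_states: dict[str, State],
    inter_cost: float = 1.0,
    intra_cost: float = 1.0,
    root_state: Optional[State] = None,
    clade_id: str = "clade",
) -> SwapReport:
    """Minimum-change reconstruction of DNAP states on a clade tree.

    Sankoff dynamic programming with configurable inter-family and
    intra-family change costs (both 1 by default, so the optimum is the
    plain parsimony count).  Backtracking ties prefer the parent's state,
    then lexicographic order, making the reported event set deterministic.
    Every leaf must be labeled; genomes without a DNAP should be pruned
    from the tree beforehand.
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in leaf_states]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")

    states = sorted({tuple(s) for s in leaf_states.values()},
                    key=lambda s: (s[0], s[1] or ""))
    cost = _unit_cost_factory(inter_cost, intra_cost)
    k = len(states)
    big = float("inf")

    node_ids: dict[TreeNode, str] = {}
    for i, node in enumerate(tree.preorder()):
        node_ids[node] = node.name if node.is_leaf else (node.name or f"node{i}")

    # upward pass
    table: dict[TreeNode, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = tuple(leaf_states[node.name])
            table[node] = [0.0 if s == obs else big for s in states]
        else:
            row = []
            for si, s in enumerate(states):
                tot = 0.0
                for c in node.children:
                    tot += min(
                        cost(s, t) + table[c][ti] for ti, t in enumerate(states)
                    )
                row.append(tot)
            table[node] = row

    root_row = table[tree.root]
    if root_state is not None:
        rs = tuple(root_state)
        if rs not in states:
            raise ValueError(f"root state {rs} not among observed states")
        min_total = root_row[states.index(rs)]
        root_choice = rs
    else:
        min_total = min(root_row)
        root_choice = next(s for s in states if root_row[states.index(s)] == min_total)

    # downward pass with deterministic tie-breaking
    assignment: dict[TreeNode, State] = {tree.root: root_choice}
    events: list[SwapEvent] = []
    for node in tree.preorder():
        s = assignment[node]
        for c in node.children:
            best_val = min(
                cost(s, t) + table[c][ti] for ti, t in enumerate(states)
            )
            candidates = [
                t for ti, t in enumerate(states)
                if cost(s, t) + table[c][ti] == best_val
            ]
            choice = s if s in candidates else candidates[0]
            assignment[c] = choice
            if choice != s:
                kind = "intra-family" if choice[0] == s[0] else "inter-family"
                events.append(SwapEvent(node_ids[c], s, choice, kind))

    return SwapReport(
        clade_id=clade_id,
        min_changes=float(min_total),
        events=events,
        node_states={node_ids[n]: st for n, st in assignment.items()},
    )
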