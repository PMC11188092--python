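"""Synthetic phage-clade generator with planted DNAP swap events.

The generator emulates the data regime the swap-detection pipeline assumes:
a clade of related phage genomes with conserved gene order, a replication
gene block containing exactly one DNAP, protein divergence produced by an
F81-type substitution process along a known ultrametric tree (the same
model the likelihood machinery uses), and rare replacement events that
substitute the DNAP — alone or en bloc with adjacent replication genes —
with a homolog from an unrelated donor family, "in situ", preserving gene
order and count.

Donor DNAPs are unrelated random sequences per family, with within-family
clades derived from a common family ancestor; catalytic motif positions are
held invariant during evolution so that reference-based annotation and
catalytic screening behave as they would on real polymerases.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dnap_annotation import MotifSpec
from .formats_io import GenomeRecord, LabelTable, ProteinRecord
from .topology_test import AA_ORDER, ProteinAlignment
from .tree import PhyloTree, TreeNode, _subtree_iter

__all__ = [
    "AA_FREQS",
    "SimConfig",
    "SwapEventSpec",
    "SimTruth",
    "SimulatedClade",
    "sample_tree",
    "preview_tree",
    "sample_swap_events",
    "evolve_genes",
    "plant_swaps",
    "emit_genomes",
    "simulate_clade",
]

# average protein amino-acid composition (order matches AA_ORDER)
AA_FREQS = np.array([
    0.080, 0.015, 0.055, 0.060, 0.040, 0.070, 0.022, 0.060, 0.060, 0.090,
    0.023, 0.040, 0.050, 0.040, 0.050, 0.070, 0.060, 0.067, 0.013, 0.035,
])
assert abs(AA_FREQS.sum() - 1.0) < 1e-12

_BETA = 1.0 / (1.0 - float(np.sum(AA_FREQS ** 2)))

# synonymous codons of the standard code, keyed by amino acid
_CODONS: dict[str, list[str]] = {}
from .orf_finder import CODON_TABLE as _CT  # noqa: E402

for _codon, _aa in _CT.items():
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

# 12-nt cassette containing stop codons in all six frames (its own
# reverse complement), spliced into both ends of every intergenic spacer
STOP_CASSETTE = "TTAATTAATTAA"

DNAP_LEN = 350
FAMILY_CLADES = {"A": ("A1", "A2"), "B": ("B1", "B2"), "C": ("C1", "C2")}

# motif layout shared by all simulated DNAP references (0-based positions)
EXO_MOTIFS = {"Exo-I": [40], "Exo-II": [52], "Exo-III": [64]}
POL_MOTIFS = {"Pol-A": [120, 121], "Pol-B": [180, 181], "Pol-C": [240, 241]}


@dataclass(frozen=True)
class SwapEventSpec:
    """A planted replacement on the edge above the clade spanning ``leaves``.

    ``mode`` is "dnap-only" or "en-bloc" (the DNAP plus the ``k`` genes
    downstream of it in the replication block).
    """

    leaves: frozenset[str]
    donor_family: str
    donor_clade: str
    mode: str = "dnap-only"
    k: int = 2


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 20
    tree_height: float = 0.25  # expected aa substitutions/site, root to leaf
    n_genes: int = 30
    gene_len_range: tuple[int, int] = (120, 300)  # aa
    intergenic_len_range: tuple[int, int] = (60, 150)  # nt
    replication_block: tuple[str, ...] = (
        "helicase", "primase", "dnap", "exonuclease", "ssb",
    )
    ancestral_family: str = "A"
    ancestral_clade: str = "A1"
    swap_events: tuple[SwapEventSpec, ...] = ()
    # when swap_events is empty, sample this many disjoint events
    n_swap_events: int = 0
    swap_modes: tuple[str, ...] = ("dnap-only", "en-bloc")
    allow_overwrite: bool = False

    def __post_init__(self):
        if self.replication_block.count("dnap") != 1:
            raise ValueError("replication block must contain exactly one dnap")
        if self.intergenic_len_range[0] < 2 * len(STOP_CASSETTE):
            raise ValueError("spacers too short for stop cassettes")


@dataclass
class SimTruth:
    tree: PhyloTree
    leaf_states: dict[str, tuple[str, str]]  # leaf -> (family, clade)
    events: list[tuple[frozenset[str], str, str, str]]  # leaves, mode, from, to
    gene_roles: list[str]
    gene_alignments: dict[int, dict[str, str]]  # gene index -> leaf -> seq


@dataclass
class SimulatedClade:
    config: SimConfig
    truth: SimTruth
    genomes: list[GenomeRecord]
    proteomes: dict[str, list[str]]  # leaf -> per-gene protein sequences
    gene_coords: dict[str, list[tuple[int, int, str]]]
    refs: list[ProteinRecord]
    labels: LabelTable
    motifs: list[MotifSpec]

    def marker_alignment(self, role: str = "terl") -> ProteinAlignment:
        """True (gap-free) alignment of the named marker gene."""
        gi = self.truth.gene_roles.index(role)
        aln = self.truth.gene_alignments[gi]
        ids = sorted(aln)
        return ProteinAlignment(ids, [aln[i] for i in ids])


# ---------------------------------------------------------------------------
# Tree sampling


def sample_tree(n_genomes: int, height: float, seed=0) -> PhyloTree:
    """Yule (pure-birth, unit rate) tree with n leaves, branch lengths
    rescaled so every root-to-leaf depth equals ``height`` exactly."""
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode()
    birth: dict[TreeNode, float] = {}
    t = 0.0
    tips: list[TreeNode] = []
    for _ in range(2):
        c = root.add_child(TreeNode())
        birth[c] = 0.0
        tips.append(c)
    while len(tips) < n_genomes:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(0, len(tips)))
        node = tips.pop(idx)
        for _ in range(2):
            c = node.add_child(TreeNode())
            birth[c] = t
            tips.append(c)
    t += rng.exponential(1.0 / len(tips))
    total = t if t > 0 else 1.0

    # assign branch lengths: internal nodes die when they split, tips at total
    for node in _subtree_iter(root):
        if node is root:
            node.length = 0.0
            continue
        death = birth[node.children[0]] if node.children else total
        node.length = (death - birth[node]) * (height / total)

    # deterministic left-to-right naming
    tree = PhyloTree(root)
    for i, leaf in enumerate(tree.leaves()):
        leaf.name = f"g{i + 1:03d}"
    return tree


def _leafset(node: TreeNode) -> frozenset[str]:
    return frozenset(n.name for n in _subtree_iter(node) if n.is_leaf)


def sample_swap_events(
    tree: PhyloTree,
    n_events: int,
    rng: np.random.Generator,
    ancestral_family: str = "A",
    modes: Sequence[str] = ("dnap-only", "en-bloc"),
    max_tries: int = 200,
) -> tuple[SwapEventSpec, ...]:
    """Choose ``n_events`` pairwise-disjoint internal edges and donor states.

    Candidate edges span between 2 leaves and half the clade; together the
    swapped clades leave at least a third of the leaves ancestral.  Each
    event receives a distinct donor (family, clade) state from the
    non-ancestral families, which makes the planted count equal the
    parsimony minimum on the true tree: every donor state labels exactly
    one clade and so demands exactly one change.
    """
    leaves = tree.leaf_names()
    donors = [
        (fam, clade)
        for fam in sorted(FAMILY_CLADES)
        if fam != ancestral_family
        for clade in FAMILY_CLADES[fam]
    ]
    if n_events > len(donors):
        raise ValueError(f"at most {len(donors)} events with distinct donors")
    candidates = [
        node for node in tree.preorder()
        if node.parent is not None and not node.is_leaf
        and 2 <= len(_leafset(node)) <= max(2, len(leaves) // 2)
    ]
    if len(candidates) < n_events:
        raise ValueError("not enough edges for the requested events")
    for _ in range(max_tries):
        chosen = list(rng.choice(len(candidates), size=n_events, replace=False))
        sets = [_leafset(candidates[i]) for i in chosen]
        if any(a & b for i, a in enumerate(sets) for b in sets[i + 1:]):
            continue
        if sum(len(s) for s in sets) > 2 * len(leaves) // 3:
            continue
        donor_order = [donors[i] for i in rng.permutation(len(donors))]
        events = []
        for s, (fam, clade) in zip(sets, donor_order):
            mode = str(rng.choice(list(modes)))
            events.append(SwapEventSpec(s, fam, clade, mode=mode, k=2))
        return tuple(events)
    raise RuntimeError("could not place disjoint swap events")


# ---------------------------------------------------------------------------
# Sequence evolution


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list(AA_ORDER), size=length - 1, p=AA_FREQS)
    return "M" + "".join(body)


def _mutate(seq: str, t: float, rng: np.random.Generator,
            invariant: frozenset[int] = frozenset()) -> str:
    """One F81 step of length t: each free site redraws from the stationary
    frequencies with probability 1 - exp(-beta*t)."""
    if t <= 0:
        return seq
    p_redraw = 1.0 - math.exp(-_BETA * t)
    n = len(seq)
    hits = np.nonzero(rng.random(n) < p_redraw)[0]
    if len(hits) == 0:
        return seq
    draws = rng.choice(list(AA_ORDER), size=len(hits), p=AA_FREQS)
    out = list(seq)
    for pos, aa in zip(hits, draws):
        if pos not in invariant and pos != 0:  # position 0 stays M
            out[pos] = aa
    return "".join(out)


def _dnap_invariant_positions() -> frozenset[int]:
    pos = set()
    for motif in (*EXO_MOTIFS.values(), *POL_MOTIFS.values()):
        pos.update(motif)
    return frozenset(pos)


def _make_donor_pool(rng: np.random.Generator):
    """Unrelated per-family DNAP ancestors with within-family clade variants
    (15% divergence from the family ancestor), plus per-family donors for
    the non-DNAP replication-block roles used in en-bloc replacements."""
    invariant = _dnap_invariant_positions()
    dnaps: dict[tuple[str, str], str] = {}
    for family in sorted(FAMILY_CLADES):
        ancestor = list(_random_protein(DNAP_LEN, rng))
        for name, positions in EXO_MOTIFS.items():
            for p in positions:
                ancestor[p] = "D"  # catalytic aspartates
        ancestor = "".join(ancestor)
        for clade in FAMILY_CLADES[family]:
            dnaps[(family, clade)] = _mutate(ancestor, 0.17, rng, invariant)
    return dnaps


def evolve_genes(
    tree: PhyloTree,
    config: SimConfig,
    rng: np.random.Generator,
    dnap_pool: dict[tuple[str, str], str],
):
    """Evolve one ancestral sequence per gene down the tree.

    Gene order is identical in every leaf.  The marker gene (role "terl")
    is gene 0; the replication block sits in the middle of the genome.
    Returns (gene_roles, node_seqs) where node_seqs maps each tree node to
    its per-gene protein list.
    """
    lo, hi = config.gene_len_range
    block = list(config.replication_block)
    if config.n_genes < len(block) + 1:
        raise ValueError("n_genes must exceed the replication block size "
                         "(gene 0 is the marker gene)")
    block_start = max(1, (config.n_genes - len(block)) // 2)
    roles = ["terl"] + ["orf"] * (config.n_genes - 1)
    for off, role in enumerate(block):
        roles[block_start + off] = role
    dnap_idx = roles.index("dnap")

    invariant_dnap = _dnap_invariant_positions()
    ancestors: list[str] = []
    for gi, role in enumerate(roles):
        if role == "dnap":
            ancestors.append(dnap_pool[(config.ancestral_family, config.ancestral_clade)])
        else:
            length = int(rng.integers(lo, hi + 1))
            ancestors.append(_random_protein(length, rng))

    node_seqs: dict[TreeNode, list[str]] = {tree.root: ancestors}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_seqs = node_seqs[node.parent]
        seqs = []
        for gi, seq in enumerate(parent_seqs):
            inv = invariant_dnap if gi == dnap_idx else frozenset()
            seqs.append(_mutate(seq, node.length, rng, inv))
        node_seqs[node] = seqs
    return roles, node_seqs, dnap_idx


def plant_swaps(
    tree: PhyloTree,
    node_seqs: dict[TreeNode, list[str]],
    roles: list[str],
    config: SimConfig,
    rng: np.random.Generator,
    dnap_pool: dict[tuple[str, str], str],
):
    """Apply the configured replacement events.

    For each event the DNAP gene (and, en bloc, the ``k`` following genes of
    the replication block) of every leaf below the event edge is replaced by
    a donor-derived sequence evolved down the remaining subtree.  Gene order
    and gene count are unchanged.  Returns the per-leaf (family, clade)
    states and the realized event list.
    """
    dnap_idx = roles.index("dnap")
    block_indices = [i for i, r in enumerate(roles) if r in config.replication_block and r != "orf"]
    nodes_by_leafset = {_leafset(n): n for n in tree.preorder() if n.parent is not None}

    event_nodes: list[tuple[TreeNode, SwapEventSpec]] = []
    for ev in config.swap_events:
        node = nodes_by_leafset.get(frozenset(ev.leaves))
        if node is None:
            raise ValueError(f"no edge spans exactly {sorted(ev.leaves)}")
        event_nodes.append((node, ev))
    # reject nested events unless overwriting is allowed
    for i, (a, _) in enumerate(event_nodes):
        for b, _ in event_nodes[i + 1:]:
            la, lb = _leafset(a), _leafset(b)
            if (la < lb or lb < la) and not config.allow_overwrite:
                raise ValueError("conflicting events on nested edges")

    leaf_states = {
        leaf: (config.ancestral_family, config.ancestral_clade)
        for leaf in tree.leaf_names()
    }
    invariant = _dnap_invariant_positions()
    events_out = []
    # apply top-down so that (with allow_overwrite) deeper events win
    event_nodes.sort(key=lambda pair: len(_leafset(pair[0])), reverse=True)
    for node, ev in event_nodes:
        donor = dnap_pool[(ev.donor_family, ev.donor_clade)]
        replacements = {dnap_idx: (donor, invariant)}
        if ev.mode == "en-bloc":
            after = [i for i in block_indices if i > dnap_idx][: ev.k]
            for gi in after:
                length = len(node_seqs[tree.root][gi])
                replacements[gi] = (_random_protein(length, rng), frozenset())
        elif ev.mode != "dnap-only":
            raise ValueError(f"unknown swap mode {ev.mode!r}")

        # evolve the donor genes down the subtree below the event edge
        sub_seqs: dict[TreeNode, dict[int, str]] = {
            node: {
                gi: _mutate(seq, node.length, rng, inv)
                for gi, (seq, inv) in replacements.items()
            }
        }
        for desc in _subtree_iter(node):
            if desc is node:
                continue
            parent_map = sub_seqs[desc.parent]
            sub_seqs[desc] = {
                gi: _mutate(s, desc.length, rng,
                            invariant if gi == dnap_idx else frozenset())
                for gi, s in parent_map.items()
            }
        for desc in _subtree_iter(node):
            for gi, s in sub_seqs[desc].items():
                node_seqs[desc][gi] = s
            if desc.is_leaf:
                leaf_states[desc.name] = (ev.donor_family, ev.donor_clade)
        events_out.append(
            (frozenset(ev.leaves), ev.mode,
             config.ancestral_family, ev.donor_family)
        )
    return leaf_states, events_out


# ---------------------------------------------------------------------------
# Genome emission


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS.get(aa, _CODONS["A"])
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons) + "TAA"


def _spacer(length: int, rng: np.random.Generator) -> str:
    mid = length - 2 * len(STOP_CASSETTE)
    middle = "".join(rng.choice(list("ACGT"), size=mid)) if mid > 0 else ""
    return STOP_CASSETTE + middle + STOP_CASSETTE


def emit_genomes(
    leaf_proteomes: dict[str, list[str]],
    config: SimConfig,
    rng: np.random.Generator,
):
    """Back-translate proteomes into nucleotide genomes.

    Every protein becomes an ATG-initiated, TAA-terminated gene (uniform
    random synonymous codons); genes are joined by random spacers carrying
    stop codons in all six frames near both ends, so no spurious ORF can
    span a gene boundary.
    """
    lo, hi = config.intergenic_len_range
    genomes = []
    coords: dict[str, list[tuple[int, int, str]]] = {}
    for leaf in sorted(leaf_proteomes):
        parts = []
        gene_coords = []
        pos = 0
        spacer = _spacer(int(rng.integers(lo, hi + 1)), rng)
        parts.append(spacer)
        pos += len(spacer)
        for protein in leaf_proteomes[leaf]:
            nt = _back_translate(protein, rng)
            gene_coords.append((pos, pos + len(nt), "+"))
            parts.append(nt)
            pos += len(nt)
            spacer = _spacer(int(rng.integers(lo, hi + 1)), rng)
            parts.append(spacer)
            pos += len(spacer)
        genomes.append(GenomeRecord(leaf, "".join(parts)))
        coords[leaf] = gene_coords
    return genomes, coords


def _reference_set(dnap_pool: dict[tuple[str, str], str]):
    import pandas as pd

    refs = []
    rows = []
    motifs = []
    for (family, clade), seq in sorted(dnap_pool.items()):
        rid = f"ref_{family}_{clade}"
        refs.append(ProteinRecord(rid, seq))
        rows.append({"protein_id": rid, "family": family, "clade_label": clade})
        for name, positions in POL_MOTIFS.items():
            motifs.append(
                MotifSpec(rid, name, [(p, seq[p]) for p in positions])
            )
        for name, positions in EXO_MOTIFS.items():
            motifs.append(MotifSpec(rid, name, [(p, "D") for p in positions]))
    labels = LabelTable(pd.DataFrame(rows))
    return refs, labels, motifs


def _streams(seed: int, n: int = 5) -> list[np.random.Generator]:
    return [np.random.default_rng([seed, k]) for k in range(n)]


def preview_tree(config: SimConfig) -> PhyloTree:
    """The exact genome tree :func:`simulate_clade` will use for this config
    (for specifying swap events against known edges)."""
    tree_rng = _streams(config.seed)[0]
    return sample_tree(config.n_genomes, config.tree_height, tree_rng)


def simulate_clade(config: SimConfig) -> SimulatedClade:
    """Run the whole generator: tree, proteomes, swaps, genomes, references."""
    tree_rng, pool_rng, event_rng, evo_rng, emit_rng = _streams(config.seed)
    tree = sample_tree(config.n_genomes, config.tree_height, tree_rng)
    dnap_pool = _make_donor_pool(pool_rng)
    if not config.swap_events and config.n_swap_events:
        config = replace(
            config,
            swap_events=sample_swap_events(
                tree,
                config.n_swap_events,
                event_rng,
                ancestral_family=config.ancestral_family,
                modes=config.swap_modes,
            ),
        )
    rng = evo_rng
    roles, node_seqs, dnap_idx = evolve_genes(tree, config, rng, dnap_pool)
    leaf_states, events = plant_swaps(
        tree, node_seqs, roles, config, rng, dnap_pool
    )
    rng = emit_rng
    leaf_proteomes = {
        n.name: node_seqs[n] for n in tree.leaves()
    }
    genomes, coords = emit_genomes(leaf_proteomes, config, rng)
    refs, labels, motifs = _reference_set(dnap_pool)
    gene_alignments = {
        gi: {leaf: seqs[gi] for leaf, seqs in leaf_proteomes.items()}
        for gi in range(config.n_genes)
    }
    truth = SimTruth(
        tree=tree,
        leaf_states=leaf_states,
        events=events,
        gene_roles=roles,
        gene_alignments=gene_alignments,
    )
    return SimulatedClade(
        config=config,
        truth=truth,
        genomes=genomes,
        proteomes=leaf_proteomes,
        gene_coords=coords,
        refs=refs,
        labels=labels,
        motifs=motifs,
    )
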