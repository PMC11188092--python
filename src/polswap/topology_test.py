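"""Per-site log-likelihoods under an F81-type protein model and the
Approximately Unbiased (AU) topology test via multiscale RELL bootstrap.

Model: equal exchangeabilities with stationary frequencies pi (a 20-state
Felsenstein-1981 analog).  Transition probabilities have the closed form

    P_ij(t) = exp(-beta t) * delta_ij + (1 - exp(-beta t)) * pi_j,
    beta = 1 / (1 - sum_k pi_k^2),

so that t is the expected number of substitutions per site.  Gaps (and X)
are treated as missing data.  Site likelihoods are computed by Felsenstein
pruning at the (arbitrary) root weighted by pi; the model is reversible, so
root placement does not affect the likelihood.

The AU test follows Shimodaira's multiscale bootstrap: per-site
log-likelihoods are resampled at several scale factors r (default 0.5..1.4),
the fraction of replicates each topology wins (bp) is transformed to normal
quantiles and regressed on d*sqrt(r) + c/sqrt(r) by weighted least squares;
p_AU = 1 - Phi(d - c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .genome_distance import DistanceMatrix
from .tree import PhyloTree, constrained_nj, midpoint_root, nj_tree

__all__ = [
    "AA_ORDER",
    "DEFAULT_SCALES",
    "ProteinAlignment",
    "SiteLnLMatrix",
    "AuResult",
    "site_lnl",
    "au_test",
    "f81_distance_matrix",
    "compare_constrained",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
LNL_FLOOR = -745.0  # ln of the smallest positive double


@dataclass
class ProteinAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def observed_freqs(self, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.full(20, pseudocount)
        for row in self.rows:
            for ch in row:
                i = _AA_IDX.get(ch)
                if i is not None:
                    counts[i] += 1
        return counts / counts.sum()


@dataclass
class SiteLnLMatrix:
    topologies: list[str]
    lnl: np.ndarray  # (n_sites, n_topologies)

    def __post_init__(self):
        self.lnl = np.asarray(self.lnl, dtype=float)
        if self.lnl.ndim != 2 or self.lnl.shape[1] != len(self.topologies):
            raise ValueError("lnl shape mismatch")
        if not np.isfinite(self.lnl).all():
            raise ValueError("non-finite site log-likelihoods")
        if self.lnl.shape[0] < 1:
            raise ValueError("need at least one site")


@dataclass
class AuResult:
    topologies: list[str]
    scales: np.ndarray
    bp: np.ndarray  # (n_topologies, n_scales)
    c: np.ndarray
    d: np.ndarray
    p_au: np.ndarray
    B: int
    seed: int


def _beta(freqs: np.ndarray) -> float:
    return 1.0 / (1.0 - float(np.sum(freqs ** 2)))


def transition_matrix(t: float, freqs: np.ndarray) -> np.ndarray:
    e = math.exp(-_beta(freqs) * max(t, 0.0))
    return e * np.eye(20) + (1.0 - e) * np.tile(freqs, (20, 1))


def _leaf_partial(row: str) -> np.ndarray:
    """(n_sites, 20) partial likelihoods; gaps/X give all-ones (missing)."""
    n = len(row)
    out = np.zeros((n, 20))
    for s, ch in enumerate(row):
        i = _AA_IDX.get(ch)
        if i is None:
            out[s, :] = 1.0
        else:
            out[s, i] = 1.0
    return out


def site_lnl(aln: ProteinAlignment, tree: PhyloTree,
             freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-site log-likelihood vector by Felsenstein pruning."""
    if freqs is None:
        freqs = aln.observed_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    tree_leaves = set(tree.leaf_names())
    if tree_leaves != set(aln.ids):
        raise ValueError("tree leaves do not match alignment taxa")

    partial: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            partial[node] = _leaf_partial(aln.row(node.name))
        else:
            prod = None
            for c in node.children:
                P = transition_matrix(c.length, freqs)
                msg = partial[c] @ P.T  # (sites, 20): sum_j P_ij L_j
                prod = msg if prod is None else prod * msg
                del partial[c]
            partial[node] = prod
    site_l = partial[tree.root] @ freqs
    with np.errstate(divide="ignore"):
        out = np.log(site_l)
    return np.maximum(out, LNL_FLOOR)


def au_test(
    m: SiteLnLMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 10000,
    seed: int = 0,
) -> AuResult:
    """Multiscale RELL bootstrap and AU p-values.

    At each scale r, ceil(r*n) site indices are resampled with replacement
    B times; each replicate awards one unit split equally among the argmax
    topologies by resampled total log-likelihood.  bp values are clipped to
    [1/(B+1), 1-1/(B+1)] before the normal-quantile regression; a topology
    with degenerate bp (0 or 1 at every scale) short-circuits to
    p = 1/(B+1) or 1 - 1/(B+1).
    """
    scales = np.asarray(list(scales), dtype=float)
    if len(np.unique(scales)) < 2:
        raise ValueError("need at least 2 distinct scales")
    lnl = m.lnl
    n_sites, n_topo = lnl.shape
    if n_topo < 2:
        raise ValueError("need at least 2 topologies")
    rng = np.random.default_rng(seed)

    bp = np.zeros((n_topo, len(scales)))
    chunk = max(1, int(2e6 // max(n_sites, 1)))
    for si, r in enumerate(scales):
        n_r = int(math.ceil(r * n_sites))
        wins = np.zeros(n_topo)
        done = 0
        while done < B:
            c = min(chunk, B - done)
            idx = rng.integers(0, n_sites, size=(c, n_r))
            sums = lnl[idx].sum(axis=1)  # (c, n_topo)
            best = sums.max(axis=1, keepdims=True)
            is_best = sums == best
            wins += (is_best / is_best.sum(axis=1, keepdims=True)).sum(axis=0)
            done += c
        bp[:, si] = wins / B

    lo, hi = 1.0 / (B + 1), 1.0 - 1.0 / (B + 1)
    p_au = np.zeros(n_topo)
    c_fit = np.zeros(n_topo)
    d_fit = np.zeros(n_topo)
    sqrt_r = np.sqrt(scales)
    X = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    for t in range(n_topo):
        raw = bp[t]
        if np.all(raw <= 0.0):
            p_au[t] = lo
            continue
        if np.all(raw >= 1.0):
            p_au[t] = hi
            continue
        bpt = np.clip(raw, lo, hi)
        z = norm.ppf(1.0 - bpt)
        # binomial variance propagated through the quantile transform
        dens = norm.pdf(z)
        w = B * dens ** 2 / (bpt * (1.0 - bpt))
        WX = X * w[:, None]
        beta_hat = np.linalg.solve(X.T @ WX, WX.T @ z)
        d_fit[t], c_fit[t] = beta_hat[0], beta_hat[1]
        p_au[t] = float(np.clip(1.0 - norm.cdf(d_fit[t] - c_fit[t]), 0.0, 1.0))

    return AuResult(
        topologies=list(m.topologies),
        scales=scales,
        bp=bp,
        c=c_fit,
        d=d_fit,
        p_au=p_au,
        B=B,
        seed=seed,
    )


def f81_distance_matrix(aln: ProteinAlignment,
                        freqs: Optional[np.ndarray] = None,
                        max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise model-corrected distances from an alignment.

    The observed proportion of differing (both-ungapped) sites p is
    corrected as t = -ln(1 - p/b) / beta with b = 1 - sum pi^2; saturated
    pairs (p >= b) are capped at ``max_distance``.
    """
    if freqs is None:
        freqs = aln.observed_freqs()
    b = 1.0 - float(np.sum(np.asarray(freqs) ** 2))
    beta = 1.0 / b
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = aln.rows[i], aln.rows[j]
            diff = same = 0
            for a, bch in zip(ri, rj):
                if a in _AA_IDX and bch in _AA_IDX:
                    if a == bch:
                        same += 1
                    else:
                        diff += 1
            total = diff + same
            p = diff / total if total else 0.0
            if p >= b:
                t = max_distance
            else:
                t = -math.log(1.0 - p / b) / beta
            d[i, j] = d[j, i] = min(t, max_distance)
    return DistanceMatrix(list(aln.ids), d)


def compare_constrained(
    aln: ProteinAlignment,
    groups: Sequence[Sequence[str]],
    dm: Optional[DistanceMatrix] = None,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 10000,
    seed: int = 0,
) -> AuResult:
    """AU comparison of the unconstrained marker tree against the tree
    constrained to keep each group monophyletic.

    Both trees are built by (constrained) neighbor joining on
    model-corrected distances; if the constraint does not change the
    unrooted topology the identical tree is used for both columns, making
    the comparison an exact tie.
    """
    if dm is None:
        dm = f81_distance_matrix(aln)
    freqs = aln.observed_freqs()
    uncon = midpoint_root(nj_tree(dm))
    con = midpoint_root(constrained_nj(dm, groups))
    if con.bipartitions() == uncon.bipartitions():
        con = uncon
    lnl = np.column_stack([
        site_lnl(aln, uncon, freqs),
        site_lnl(aln, con, freqs),
    ])
    m = SiteLnLMatrix(["unconstrained", "constrained"], lnl)
    return au_test(m, scales=scales, B=B, seed=seed)
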