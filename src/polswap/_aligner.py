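"""Numba-accelerated Smith–Waterman scoring kernel.

Used for the all-vs-all best-hit searches, where only the optimal local
alignment score is needed.  Full alignments (for coverage and identity of
the retained pairs) go through Biopython's PairwiseAligner configured with
identical scoring, so the two routes agree on the optimal score.

Gap convention: a gap of length k costs open + k*extend (the BLAST
convention; with open=11, extend=1 a length-1 gap costs 12).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

_blosum = substitution_matrices.load("BLOSUM62")
BLOSUM62 = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int64)
for _i, _a in enumerate(AA_ALPHABET):
    for _j, _b in enumerate(AA_ALPHABET):
        BLOSUM62[_i, _j] = int(_blosum[_a][_b])


def encode(seq: str) -> np.ndarray:
    """Map an amino-acid string to BLOSUM62 row indices (unknowns -> X)."""
    x = _AA_INDEX["X"]
    return np.array([_AA_INDEX.get(c, x) for c in seq], dtype=np.int64)


@njit(cache=True)
def sw_score(a: np.ndarray, b: np.ndarray, matrix: np.ndarray,
             gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score with affine gaps.

    A gap of length k costs gap_open + k*gap_extend.
    """
    n, m = a.shape[0], b.shape[0]
    neg = -10 ** 9
    h_prev = np.zeros(m + 1, dtype=np.int64)
    e_row = np.full(m + 1, neg, dtype=np.int64)
    best = 0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, dtype=np.int64)
        f = neg
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_row[j] = max(h_prev[j] - first, e_row[j] - gap_extend)
            f = max(h_cur[j - 1] - first, f - gap_extend)
            diag = h_prev[j - 1] + matrix[ai, b[j - 1]]
            h = diag
            if e_row[j] > h:
                h = e_row[j]
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
    return best
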