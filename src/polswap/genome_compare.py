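"""Fragment-based average nucleotide identity (ANI).

Each genome is split into consecutive non-overlapping fragments (default
1000 nt; a trailing short fragment is discarded).  Every fragment is mapped
to the other genome on both strands — candidate placement by shared-k-mer
diagonal seeding, then local alignment (match +1, mismatch -1, gap of
length k costs 5 + 2k) within the seeded window.  Fragments aligning with
identity >= 0.7 over >= 70% of their length are retained; fragments are
paired by reciprocal best placement, and ANI is 100 x the mean identity
over reciprocal pairs, averaged over both directions.  With no retained
fragments the pair is flagged below detection.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

from Bio.Align import PairwiseAligner

from .formats_io import GenomeRecord
from .orf_finder import revcomp

__all__ = ["AniResult", "ani"]

SEED_K = 11


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: Optional[float]  # percent; None when below detection
    n_fragments_used: int
    fragment_len: int

    @property
    def below_detection(self) -> bool:
        return self.ani is None


def _make_dna_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -7  # first gap position: 5 + 2
    aligner.extend_gap_score = -2
    return aligner


_DNA_ALIGNER = _make_dna_aligner()


def _kmer_index(seq: str, k: int = SEED_K) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _best_window(fragment: str, index: dict[str, list[int]],
                 target_len: int, k: int = SEED_K,
                 band: int = 100) -> Optional[tuple[int, int]]:
    """Find the best-supported diagonal band and return the target window."""
    votes: dict[int, int] = defaultdict(int)
    for i in range(len(fragment) - k + 1):
        for pos in index.get(fragment[i : i + k], ()):
            votes[(pos - i) // band] += 1
    if not votes:
        return None
    best_bin = max(votes, key=lambda b: (votes[b], -b))
    diag = best_bin * band
    margin = band + 50
    start = max(diag - margin, 0)
    end = min(diag + len(fragment) + margin, target_len)
    if end <= start:
        return None
    return start, end


def _align_fragment(fragment: str, target: str,
                    index_f: dict[str, list[int]],
                    index_r: dict[str, list[int]]) -> Optional[tuple[float, float, int]]:
    """Best placement of a fragment on either strand of the target.

    Returns (identity, coverage, target_midpoint) or None if unseeded.
    """
    best = None
    for strand, index in (("+", index_f), ("-", index_r)):
        win = _best_window(fragment, index, len(target))
        if win is None:
            continue
        start, end = win
        tseq = target if strand == "+" else revcomp(target)
        window = tseq[start:end]
        alignments = _DNA_ALIGNER.align(fragment, window)
        aln = alignments[0]
        matches = 0
        cols = 0
        for (qs, qe), (ss, se) in zip(*aln.aligned):
            cols += qe - qs
            for qi, si in zip(range(qs, qe), range(ss, se)):
                if fragment[qi] == window[si]:
                    matches += 1
        if cols == 0:
            continue
        identity = matches / cols
        cov = cols / len(fragment)
        mid_local = (aln.aligned[1][0][0] + aln.aligned[1][-1][1]) // 2
        mid = start + mid_local
        if strand == "-":
            mid = len(target) - 1 - mid
        score = aln.score
        if best is None or score > best[0]:
            best = (score, identity, cov, mid)
    if best is None:
        return None
    return best[1], best[2], best[3]


def _direction(a: GenomeRecord, b: GenomeRecord, fragment_len: int,
               min_id: float, min_cov: float):
    """Map A-fragments onto B. Returns {a_frag_idx: (b_frag_idx, identity)}."""
    index_f = _kmer_index(b.seq)
    index_r = _kmer_index(revcomp(b.seq))
    out = {}
    n_frags = a.length // fragment_len
    for i in range(n_frags):
        frag = a.seq[i * fragment_len : (i + 1) * fragment_len]
        res = _align_fragment(frag, b.seq, index_f, index_r)
        if res is None:
            continue
        identity, cov, mid = res
        if identity < min_id or cov < min_cov:
            continue
        out[i] = (mid // fragment_len, identity)
    return out


def ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_len: int = 1000,
    min_frag_identity: float = 0.7,
    min_frag_cov: float = 0.7,
) -> AniResult:
    """Reciprocal-best-fragment ANI between two genomes (percent)."""
    if a.length < fragment_len or b.length < fragment_len:
        raise ValueError("genomes shorter than one fragment")
    ab = _direction(a, b, fragment_len, min_frag_identity, min_frag_cov)
    ba = _direction(b, a, fragment_len, min_frag_identity, min_frag_cov)

    identities = []
    for i, (j, id_ab) in ab.items():
        back = ba.get(j)
        if back is not None and back[0] == i:
            identities.append((id_ab + back[1]) / 2.0)
    if not identities:
        return AniResult(a.id, b.id, None, 0, fragment_len)
    value = 100.0 * sum(identities) / len(identities)
    return AniResult(a.id, b.id, value, len(identities), fragment_len)
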