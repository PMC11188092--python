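"""Pairwise protein alignment, reciprocal-best-hit detection between ORF
complements, and genome coverage accounting.

The aligner is a local Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1; a gap of length k costs 11 + k).  Raw scores S are
converted to bit scores S' = (lambda*S - ln K) / ln 2 using the gapped
BLOSUM62 constants lambda = 0.267, K = 0.041, and to E-values
E = search_space * 2**(-S').  The default search space for a query of
length q against a database of n subjects of mean length m is n * m * q,
a monotone surrogate for the BLAST search space.

Best-hit searches may optionally be seeded with a shared k-mer count
prefilter (``prefilter_min_kmers``), analogous to BLAST's word seeding:
subject candidates sharing fewer than the requested number of k-mers with
the query are not scored.  The exhaustive mode (default) scores every pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from ._aligner import BLOSUM62, encode, sw_score
from .formats_io import GenomeRecord, ProteinRecord
from .orf_finder import Orf, OrfSet

__all__ = [
    "AlignmentHit",
    "RbhPair",
    "CoverageResult",
    "LAMBDA",
    "LNK",
    "score_pair",
    "align_pair",
    "reciprocal_best_hits",
    "coverage",
]

LAMBDA = 0.267
K_PARAM = 0.041
LNK = math.log(K_PARAM)

GAP_OPEN = 11
GAP_EXTEND = 1


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython scores the first gap position with open_gap_score and each
    # further position with extend_gap_score: a length-k gap costs
    # 12 + (k-1)*1 = 11 + k, matching the kernel's convention.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    bit_score: float
    evalue: float
    query_cov: float
    identity: float

    def __post_init__(self):
        assert self.evalue >= 0
        assert 0.0 <= self.query_cov <= 1.0 + 1e-9


@dataclass
class RbhPair:
    orf_a: Orf
    orf_b: Orf
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit


@dataclass
class CoverageResult:
    c_ab: int
    c_ba: int
    l_a: int
    l_b: int

    def __post_init__(self):
        if not (0 <= self.c_ab <= self.l_a and 0 <= self.c_ba <= self.l_b):
            raise ValueError("coverage exceeds genome length")


def bit_score(raw_score: float) -> float:
    return (LAMBDA * raw_score - LNK) / math.log(2.0)


def evalue_from_bits(bits: float, search_space: float) -> float:
    return search_space * 2.0 ** (-bits)


def score_pair(query_seq: str, subject_seq: str) -> int:
    """Optimal local-alignment raw score (fast, score only)."""
    return int(sw_score(encode(query_seq), encode(subject_seq), BLOSUM62,
                        GAP_OPEN, GAP_EXTEND))


def align_pair(query: ProteinRecord, subject: ProteinRecord,
               search_space: float) -> AlignmentHit:
    """Full local alignment of two proteins with hit statistics.

    ``query_cov`` is the fraction of query residues in aligned (residue vs
    residue) columns; ``identity`` is the fraction of those columns with
    identical residues.
    """
    if not query.seq or not subject.seq:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(query.seq, subject.seq)[0]
    raw = alignment.score
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        aligned_cols += qe - qs
        for qi, si in zip(range(qs, qe), range(ss, se)):
            if query.seq[qi] == subject.seq[si]:
                matches += 1
    bits = bit_score(raw)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        score=float(raw),
        bit_score=bits,
        evalue=evalue_from_bits(bits, search_space),
        query_cov=aligned_cols / len(query.seq),
        identity=(matches / aligned_cols) if aligned_cols else 0.0,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _best_hits(queries: Sequence[ProteinRecord],
               subjects: Sequence[ProteinRecord],
               prefilter_min_kmers: Optional[int],
               kmer_size: int) -> dict[str, str]:
    """Map each query id to its best-scoring subject id (ties to the
    lexicographically lower subject id)."""
    enc_q = [encode(p.seq) for p in queries]
    enc_s = [encode(p.seq) for p in subjects]
    if prefilter_min_kmers is not None:
        kq = [_kmer_set(p.seq, kmer_size) for p in queries]
        ks = [_kmer_set(p.seq, kmer_size) for p in subjects]
    best: dict[str, str] = {}
    for i, q in enumerate(queries):
        best_score = None
        best_id = None
        for j, s in enumerate(subjects):
            if prefilter_min_kmers is not None:
                if len(kq[i] & ks[j]) < prefilter_min_kmers:
                    continue
            sc = int(sw_score(enc_q[i], enc_s[j], BLOSUM62, GAP_OPEN, GAP_EXTEND))
            if (
                best_score is None
                or sc > best_score
                or (sc == best_score and s.id < best_id)
            ):
                best_score, best_id = sc, s.id
        if best_id is not None:
            best[q.id] = best_id
    return best


def reciprocal_best_hits(
    orfs_a: OrfSet,
    orfs_b: OrfSet,
    min_query_cov: float = 0.5,
    max_evalue: float = 1e-4,
    prefilter_min_kmers: Optional[int] = None,
    kmer_size: int = 4,
) -> list[RbhPair]:
    """Reciprocal best hits between two ORF complements.

    A pair (x, y) is reported iff y is x's best-scoring hit among B and x is
    y's best among A (ties broken by lower subject id), and both directional
    hits satisfy the query-coverage and E-value thresholds.
    """
    prot_a = {o.id: (o, o.to_protein_record()) for o in orfs_a}
    prot_b = {o.id: (o, o.to_protein_record()) for o in orfs_b}
    if not prot_a or not prot_b:
        return []
    recs_a = [p for _, p in prot_a.values()]
    recs_b = [p for _, p in prot_b.values()]

    fwd = _best_hits(recs_a, recs_b, prefilter_min_kmers, kmer_size)
    rev = _best_hits(recs_b, recs_a, prefilter_min_kmers, kmer_size)

    mean_len_b = float(np.mean([len(p.seq) for p in recs_b]))
    mean_len_a = float(np.mean([len(p.seq) for p in recs_a]))

    pairs: list[RbhPair] = []
    for aid, bid in sorted(fwd.items()):
        if rev.get(bid) != aid:
            continue
        orf_a, rec_a = prot_a[aid]
        orf_b, rec_b = prot_b[bid]
        space_ab = len(recs_b) * mean_len_b * len(rec_a.seq)
        space_ba = len(recs_a) * mean_len_a * len(rec_b.seq)
        hit_ab = align_pair(rec_a, rec_b, space_ab)
        # the local alignment is symmetric; reuse its statistics
        hit_ba = AlignmentHit(
            query_id=bid,
            subject_id=aid,
            score=hit_ab.score,
            bit_score=hit_ab.bit_score,
            evalue=evalue_from_bits(hit_ab.bit_score, space_ba),
            query_cov=hit_ab.query_cov * len(rec_a.seq) / len(rec_b.seq),
            identity=hit_ab.identity,
        )
        if (
            hit_ab.query_cov >= min_query_cov
            and hit_ba.query_cov >= min_query_cov
            and hit_ab.evalue <= max_evalue
            and hit_ba.evalue <= max_evalue
        ):
            pairs.append(RbhPair(orf_a, orf_b, hit_ab, hit_ba))
    return pairs


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def coverage(rbh_pairs: Sequence[RbhPair], genome_a: GenomeRecord,
             genome_b: GenomeRecord) -> CoverageResult:
    """Total genome length covered by RBH-participating ORFs, per side.

    Overlapping ORF intervals are counted once (interval union).
    """
    ints_a = [(p.orf_a.start, p.orf_a.end) for p in rbh_pairs]
    ints_b = [(p.orf_b.start, p.orf_b.end) for p in rbh_pairs]
    return CoverageResult(
        c_ab=_union_length(ints_a),
        c_ba=_union_length(ints_b),
        l_a=genome_a.length,
        l_b=genome_b.length,
    )
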