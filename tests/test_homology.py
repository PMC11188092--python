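"""Aligner, RBH and coverage behavior against independent oracles."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from polswap.formats_io import GenomeRecord, ProteinRecord
from polswap.homology import (
    GAP_EXTEND,
    GAP_OPEN,
    align_pair,
    coverage,
    reciprocal_best_hits,
    score_pair,
)
from polswap.orf_finder import Orf, OrfSet

AAS = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def dp_local_score(a: str, b: str) -> int:
    """Quadratic-time affine Smith-Waterman oracle (three explicit DP
    matrices); a gap of length k costs GAP_OPEN + k * GAP_EXTEND."""
    n, m = len(a), len(b)
    neg = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=int)
    E = np.full((n + 1, m + 1), neg, dtype=int)
    F = np.full((n + 1, m + 1), neg, dtype=int)
    best = 0
    first = GAP_OPEN + GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - GAP_EXTEND)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - GAP_EXTEND)
            sub = H[i - 1][j - 1] + int(_B62[a[i - 1]][b[j - 1]])
            H[i][j] = max(0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_protein(rng, lo=30, hi=80) -> str:
    return "".join(rng.choice(list(AAS), size=rng.integers(lo, hi)))


def mutate_protein(seq, rate, rng) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = rng.choice(list(AAS))
    return "".join(out)


class TestAlignPair:
    def test_identical_sequences(self):
        seq = "MKLVINSGQWERTYHAD" * 6
        hit = align_pair(ProteinRecord("a", seq), ProteinRecord("b", seq), 1e6)
        assert hit.identity == 1.0
        assert hit.query_cov == 1.0
        assert hit.evalue < 1e-10

    def test_evalue_vanishes_with_search_space(self):
        seq = "MKLVINSGQWERTYHAD"
        hit = align_pair(ProteinRecord("a", seq), ProteinRecord("b", seq), 0.0)
        assert hit.evalue == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            a, b = random_protein(rng), random_protein(rng)
            assert score_pair(a, b) == dp_local_score(a, b)
        # related pairs exercise the gap states harder
        a = random_protein(rng, 60, 90)
        b = mutate_protein(a, 0.3, rng)
        assert score_pair(a, b) == dp_local_score(a, b)

    def test_full_aligner_agrees_with_score_kernel(self):
        rng = np.random.default_rng(42)
        a = random_protein(rng, 60, 90)
        b = mutate_protein(a, 0.4, rng)
        hit = align_pair(ProteinRecord("a", a), ProteinRecord("b", b), 1.0)
        assert hit.score == score_pair(a, b)


def _orf_set(genome_id: str, proteins: list[str]) -> OrfSet:
    orfs = []
    pos = 100
    for p in proteins:
        nt = 3 * len(p) + 3
        orfs.append(Orf(genome_id, pos, pos + nt, "+", 0, p))
        pos += nt + 100
    return OrfSet(genome_id, orfs)


class TestReciprocalBestHits:
    def test_identical_proteomes_pair_everything(self):
        rng = np.random.default_rng(0)
        prots = [random_protein(rng, 60, 100) for _ in range(6)]
        pairs = reciprocal_best_hits(_orf_set("a", prots), _orf_set("b", prots))
        assert len(pairs) == 6
        for p in pairs:
            assert p.orf_a.protein == p.orf_b.protein

    def test_empty_side_gives_empty_list(self):
        rng = np.random.default_rng(1)
        prots = [random_protein(rng) for _ in range(3)]
        assert reciprocal_best_hits(_orf_set("a", prots), OrfSet("b", [])) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_mutual_argmax_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        base = [random_protein(rng, 40, 90) for _ in range(12)]
        prots_a = base
        prots_b = [mutate_protein(p, 0.45, rng) for p in base]
        rng.shuffle(prots_b)
        set_a, set_b = _orf_set("a", prots_a), _orf_set("b", prots_b)

        # oracle: all-vs-all DP scores, mutual argmax, ties to lower id
        def best(qset, sset):
            out = {}
            for q in qset:
                scored = sorted(
                    ((dp_local_score(q.protein, s.protein), s.id) for s in sset),
                    key=lambda t: (-t[0], t[1]),
                )
                out[q.id] = scored[0][1]
            return out

        fwd, rev = best(set_a, set_b), best(set_b, set_a)
        expected = {
            (a, b) for a, b in fwd.items() if rev.get(b) == a
        }
        got = {
            (p.orf_a.id, p.orf_b.id)
            for p in reciprocal_best_hits(
                set_a, set_b, min_query_cov=0.0, max_evalue=np.inf
            )
        }
        assert got == expected

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        base = [random_protein(rng, 50, 80) for _ in range(8)]
        other = [mutate_protein(p, 0.3, rng) for p in base]
        sa, sb = _orf_set("a", base), _orf_set("b", other)
        ab = {(p.orf_a.id, p.orf_b.id) for p in reciprocal_best_hits(sa, sb)}
        ba = {(p.orf_b.id, p.orf_a.id) for p in reciprocal_best_hits(sb, sa)}
        assert ab == ba

    def test_unrelated_proteomes_fail_evalue_threshold(self):
        rng = np.random.default_rng(4)
        sa = _orf_set("a", [random_protein(rng, 60, 90) for _ in range(8)])
        sb = _orf_set("b", [random_protein(rng, 60, 90) for _ in range(8)])
        assert reciprocal_best_hits(sa, sb) == []


class TestCoverage:
    def _genomes(self, length=10000):
        return GenomeRecord("a", "A" * length), GenomeRecord("b", "A" * length)

    def _pair(self, ia, ib):
        oa = Orf("a", ia[0], ia[1], "+", 0, "M")
        ob = Orf("b", ib[0], ib[1], "+", 0, "M")
        return type("P", (), {"orf_a": oa, "orf_b": ob})()

    def test_single_orf(self):
        ga, gb = self._genomes()
        cov = coverage([self._pair((0, 300), (0, 300))], ga, gb)
        assert cov.c_ab == 300 and cov.c_ba == 300

    def test_overlaps_counted_once(self):
        ga, gb = self._genomes()
        cov = coverage(
            [self._pair((0, 300), (0, 300)), self._pair((150, 450), (500, 800))],
            ga, gb,
        )
        assert cov.c_ab == 450
        assert cov.c_ba == 600

    @pytest.mark.parametrize("seed", range(5))
    def test_union_matches_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ga, gb = self._genomes(5000)
        pairs = []
        mask_a = np.zeros(5000, bool)
        mask_b = np.zeros(5000, bool)
        for _ in range(12):
            sa = int(rng.integers(0, 4500))
            ea = sa + int(rng.integers(30, 500))
            sb = int(rng.integers(0, 4500))
            eb = sb + int(rng.integers(30, 500))
            mask_a[sa:ea] = True
            mask_b[sb:eb] = True
            pairs.append(self._pair((sa, ea), (sb, eb)))
        cov = coverage(pairs, ga, gb)
        assert cov.c_ab == int(mask_a.sum())
        assert cov.c_ba == int(mask_b.sum())
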