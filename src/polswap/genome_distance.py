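"""The RBH-coverage genome distance and the all-pairs distance matrix.

For genomes A and B with lengths L_A, L_B, let C_AB be the total length of
the part of A covered by ORFs having reciprocal best hits in B (and C_BA
symmetrically).  The distance is

    D(A, B) = 1 - (C_AB + C_BA) / (L_A + L_B)

clamped to [0, 1].  The diagonal of the matrix is fixed at 0 by definition
(the formula applied to (A, A) would yield the intergenic fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeRecord
from .homology import CoverageResult, coverage, reciprocal_best_hits
from .orf_finder import OrfSet

__all__ = ["DistanceMatrix", "genome_distance", "distance_matrix"]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def validate(self) -> None:
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("entries outside [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(t) for t in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])


def genome_distance(cov: CoverageResult) -> float:
    """D = 1 - (C_AB + C_BA) / (L_A + L_B), clamped to [0, 1]."""
    if cov.l_a <= 0 or cov.l_b <= 0:
        raise ValueError("genome lengths must be positive")
    d = 1.0 - (cov.c_ab + cov.c_ba) / (cov.l_a + cov.l_b)
    return min(max(d, 0.0), 1.0)


def distance_matrix(
    genomes: Sequence[GenomeRecord],
    orf_sets: Sequence[OrfSet],
    min_query_cov: float = 0.5,
    max_evalue: float = 1e-4,
    prefilter_min_kmers: Optional[int] = None,
) -> DistanceMatrix:
    """All-pairs RBH-coverage distances.

    Each unordered genome pair is processed independently
    (RBH -> coverage -> distance); the diagonal is 0.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    by_id = {os.genome_id: os for os in orf_sets}
    missing = set(ids) - set(by_id)
    if missing:
        raise ValueError(f"missing ORF sets for genomes: {sorted(missing)}")

    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = reciprocal_best_hits(
                by_id[ids[i]],
                by_id[ids[j]],
                min_query_cov=min_query_cov,
                max_evalue=max_evalue,
                prefilter_min_kmers=prefilter_min_kmers,
            )
            cov = coverage(pairs, genomes[i], genomes[j])
            d[i, j] = d[j, i] = genome_distance(cov)
    return DistanceMatrix(ids, d)
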