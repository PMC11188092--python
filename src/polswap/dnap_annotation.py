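"""DNAP family and clade annotation from labeled reference proteins, plus
catalytic-residue screening.

Each predicted protein is aligned against every labeled reference; the best
hit by bit score (E-value at most the threshold, default 1e-4) transfers the
reference's family (A, B, C, divA1, divA2) and in-family clade label.
Catalytic motifs — e.g. the palm-domain Pol motifs A/B/C and the
3'-exonuclease motifs I/II/III (catalytic aspartates) — are read through the
query-to-reference alignment: a motif is intact when every motif position
aligns to the required residue class, degraded when any aligned position
mismatches, and absent when positions fall in gaps or outside the aligned
span.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .formats_io import LabelTable, ProteinRecord
from .homology import align_pair, score_pair

logger = logging.getLogger(__name__)

__all__ = [
    "MotifSpec",
    "DnapCall",
    "GenomeDnapSummary",
    "assign_family",
    "check_catalytic",
    "bind_motifs",
    "classify_heterogeneity",
    "filter_active",
]

FAMILIES = ("A", "B", "C", "divA1", "divA2")


@dataclass
class MotifSpec:
    """Required residues at reference positions (0-based) for one motif.

    ``ref_seq`` is filled in by :func:`bind_motifs`; catalytic screening
    needs it to align queries against the reference.
    """

    reference_id: str
    name: str
    positions: list[tuple[int, str]]  # (position, allowed residue string)
    ref_seq: Optional[str] = None


@dataclass
class DnapCall:
    protein_id: str
    genome_id: str
    family: Optional[str]  # None = no qualifying reference hit
    clade_label: Optional[str]
    best_ref_id: Optional[str]
    evalue: Optional[float]
    bit_score: Optional[float] = None
    ref_coverage: Optional[float] = None  # aligned columns / reference length
    catalytic: dict[str, str] = field(default_factory=dict)  # motif -> status

    def __post_init__(self):
        if self.family is None:
            assert self.clade_label is None


@dataclass
class GenomeDnapSummary:
    genome_id: str
    status: str  # "no-DNAP" | "single-DNAP" | "multi-DNAP"
    families: list[str]  # sorted distinct families among the calls
    calls: list[DnapCall] = field(default_factory=list)

    @property
    def state(self) -> Optional[tuple[str, Optional[str]]]:
        """(family, clade) of the single DNAP, for single-DNAP genomes."""
        if self.status != "single-DNAP":
            return None
        call = self.calls[0]
        return (call.family, call.clade_label)


def assign_family(
    protein: ProteinRecord,
    refs: Sequence[ProteinRecord],
    labels: LabelTable,
    max_evalue: float = 1e-4,
    prefilter_min_kmers: Optional[int] = None,
) -> DnapCall:
    """Best-hit family/clade transfer from labeled references.

    The best reference is chosen by raw alignment score with ties broken by
    the lower reference id; if its E-value exceeds the threshold the protein
    is called family ``None``.
    """
    if not refs:
        raise ValueError("empty reference set")
    best_score = None
    best_ref = None
    for ref in refs:
        if prefilter_min_kmers is not None:
            k = 4
            shared = len(
                {protein.seq[i:i + k] for i in range(len(protein.seq) - k + 1)}
                & {ref.seq[i:i + k] for i in range(len(ref.seq) - k + 1)}
            )
            if shared < prefilter_min_kmers:
                continue
        sc = score_pair(protein.seq, ref.seq)
        if best_score is None or sc > best_score or (
            sc == best_score and ref.id < best_ref.id
        ):
            best_score, best_ref = sc, ref
    no_call = DnapCall(protein.id, protein.genome_id, None, None, None, None)
    if best_ref is None:
        return no_call
    mean_len = sum(len(r.seq) for r in refs) / len(refs)
    space = len(refs) * mean_len * len(protein.seq)
    hit = align_pair(protein, best_ref, space)
    if hit.evalue > max_evalue:
        return no_call
    aligned_cols = hit.query_cov * len(protein.seq)
    return DnapCall(
        protein_id=protein.id,
        genome_id=protein.genome_id,
        family=labels.family_of(best_ref.id),
        clade_label=labels.clade_of(best_ref.id),
        best_ref_id=best_ref.id,
        evalue=hit.evalue,
        bit_score=hit.bit_score,
        ref_coverage=aligned_cols / len(best_ref.seq),
    )


_motif_aligner = PairwiseAligner()
_motif_aligner.mode = "local"
_motif_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_motif_aligner.open_gap_score = -12
_motif_aligner.extend_gap_score = -1


def check_catalytic(
    protein: ProteinRecord,
    call: DnapCall,
    motifs: Sequence[MotifSpec],
) -> DnapCall:
    """Screen the catalytic motifs of the call's best reference.

    Updates ``call.catalytic`` with one status per motif:
    intact / degraded / absent.
    """
    if call.family is None or call.best_ref_id is None:
        raise ValueError("check_catalytic requires a family call")
    ref_motifs = [m for m in motifs if m.reference_id == call.best_ref_id]
    if not ref_motifs:
        return call
    if any(m.ref_seq is None for m in ref_motifs):
        raise ValueError(
            "MotifSpec entries must be bound to reference sequences via "
            "bind_motifs() before catalytic screening"
        )
    ref_seq = ref_motifs[0].ref_seq

    alignment = _motif_aligner.align(protein.seq, ref_seq)[0]
    # map reference position -> query residue (None when gapped/uncovered)
    ref_to_query: dict[int, str] = {}
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        for qi, si in zip(range(qs, qe), range(ss, se)):
            ref_to_query[si] = protein.seq[qi]

    for motif in ref_motifs:
        statuses = []
        for pos, allowed in motif.positions:
            residue = ref_to_query.get(pos)
            if residue is None:
                statuses.append("absent")
            elif residue in allowed:
                statuses.append("intact")
            else:
                statuses.append("degraded")
        if any(s == "degraded" for s in statuses):
            call.catalytic[motif.name] = "degraded"
        elif any(s == "absent" for s in statuses):
            call.catalytic[motif.name] = "absent"
        else:
            call.catalytic[motif.name] = "intact"
    return call


def bind_motifs(motifs: Sequence[MotifSpec], refs: Sequence[ProteinRecord]) -> list[MotifSpec]:
    """Attach reference sequences to motif specs (validates positions)."""
    by_id = {r.id: r for r in refs}
    bound = []
    for m in motifs:
        ref = by_id.get(m.reference_id)
        if ref is None:
            raise ValueError(f"motif references unknown protein {m.reference_id}")
        for pos, _ in m.positions:
            if not (0 <= pos < len(ref.seq)):
                raise ValueError(
                    f"motif {m.name} position {pos} outside reference {ref.id}"
                )
        m.ref_seq = ref.seq
        bound.append(m)
    return bound


def filter_active(
    calls: Sequence[DnapCall],
    min_ref_cov: float = 0.8,
    pol_motif_prefix: str = "Pol",
) -> list[DnapCall]:
    """Retain calls predicted catalytically active: all polymerase motifs
    intact and alignment covering at least ``min_ref_cov`` of the reference.

    Calls without screened Pol motifs are retained (no evidence against
    activity); exonuclease motif status does not affect retention.
    """
    out = []
    for call in calls:
        if call.family is None:
            continue
        if call.ref_coverage is not None and call.ref_coverage < min_ref_cov:
            continue
        pol = [s for name, s in call.catalytic.items()
               if name.startswith(pol_motif_prefix)]
        if pol and any(s != "intact" for s in pol):
            continue
        out.append(call)
    return out


def classify_heterogeneity(
    calls: Sequence[DnapCall],
    genome_ids: Optional[Sequence[str]] = None,
) -> dict[str, GenomeDnapSummary]:
    """Per-genome DNAP complement summary.

    Genomes are labeled no-DNAP, single-DNAP (one family among the calls,
    even if multiple copies), or multi-DNAP (two or more distinct families).
    ``genome_ids`` extends the output to genomes without any call.
    """
    by_genome: dict[str, list[DnapCall]] = defaultdict(list)
    for call in calls:
        if call.family is not None:
            by_genome[call.genome_id].append(call)
    ids = set(by_genome)
    if genome_ids is not None:
        ids |= set(genome_ids)
    out: dict[str, GenomeDnapSummary] = {}
    for gid in sorted(ids):
        gcalls = by_genome.get(gid, [])
        families = sorted({c.family for c in gcalls})
        if not families:
            status = "no-DNAP"
        elif len(families) == 1:
            status = "single-DNAP"
        else:
            status = "multi-DNAP"
        out[gid] = GenomeDnapSummary(gid, status, families, gcalls)
    return out
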