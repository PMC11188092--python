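"""Six-frame ORF extraction.

The ORF complement of a genome is the set of ATG-initiated, stop-terminated
reading frames of at least ``min_orf_len`` nucleotides (stop codon included),
with nested ORFs removed: an ORF is dropped when its genomic interval is
strictly contained in a longer retained ORF's interval, on either strand.
Minus-strand ORFs are reported in genome (plus-strand) coordinates.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .formats_io import GenomeRecord, ProteinRecord

__all__ = ["Orf", "OrfSet", "find_orfs", "translate", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")

# standard genetic code (translation table 11 codon assignments)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, strand: str = "+") -> str:
    """Translate a nucleotide sequence under the standard genetic code.

    Stop codons yield no character; any codon containing a character outside
    {A,C,G,T} translates to X.  The length must be divisible by 3.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    seq = nt_seq.upper()
    if strand == "-":
        seq = revcomp(seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            out.append("X")
        elif aa != "*":
            out.append(aa)
    return "".join(out)


@dataclass(frozen=True)
class Orf:
    """An open reading frame in 0-based half-open genomic coordinates.

    ``start``/``end`` always refer to the plus strand; for minus-strand ORFs
    the reading direction runs from ``end`` toward ``start``.  ``frame`` is
    the start offset modulo 3 in the reading-strand orientation.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def id(self) -> str:
        return f"{self.genome_id}|{self.start}-{self.end}{self.strand}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_protein_record(self) -> ProteinRecord:
        return ProteinRecord(
            id=self.id,
            seq=self.protein,
            genome_id=self.genome_id,
            coords=(self.start, self.end, self.strand),
        )


@dataclass
class OrfSet:
    genome_id: str
    orfs: list[Orf] = field(default_factory=list)

    def __post_init__(self):
        self.orfs = sorted(self.orfs, key=lambda o: (o.start, o.end, o.strand))

    def __len__(self) -> int:
        return len(self.orfs)

    def __iter__(self):
        return iter(self.orfs)

    def proteins(self) -> list[ProteinRecord]:
        return [o.to_protein_record() for o in self.orfs]


def _scan_strand(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All ATG→stop ORFs of length >= min_len on the given sequence, as
    (start, end, frame) in that sequence's own coordinates."""
    n = len(seq)
    out = []
    for frame in range(3):
        stops = []
        starts = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                stops.append(i)
            elif codon == "ATG":
                starts.append(i)
        for s in starts:
            k = bisect_right(stops, s)
            if k == len(stops):
                continue  # runs off the end: not stop-terminated
            e = stops[k] + 3
            if e - s >= min_len:
                out.append((s, e, frame))
    return out


def find_orfs(genome: GenomeRecord, min_orf_len: int = 75) -> OrfSet:
    """Extract the non-nested ORF complement of a genome.

    All six frames are scanned; each ORF runs from an ATG through the first
    in-frame stop (stop included).  ORFs are then filtered for strict
    interval containment across both strands, longer ORFs winning and ties
    on length resolved in favor of the lower start coordinate.
    """
    if not genome.seq:
        raise ValueError("empty genome")
    seq = genome.seq.upper()
    n = len(seq)
    raw: list[Orf] = []
    for s, e, frame in _scan_strand(seq, min_orf_len):
        raw.append(
            Orf(genome.id, s, e, "+", frame, translate(seq[s:e], "+"))
        )
    rc = revcomp(seq)
    for s, e, frame in _scan_strand(rc, min_orf_len):
        # map back to plus-strand coordinates
        raw.append(
            Orf(genome.id, n - e, n - s, "-", frame, translate(rc[s:e], "+"))
        )

    kept = _remove_nested(raw)
    return OrfSet(genome.id, kept)


def _remove_nested(orfs: list[Orf]) -> list[Orf]:
    """Drop ORFs whose interval is strictly contained in a longer retained
    ORF's interval (either strand)."""
    order = sorted(orfs, key=lambda o: (-o.length, o.start, o.end, o.strand))
    kept: list[Orf] = []
    for orf in order:
        contained = False
        for big in kept:
            if (
                big.start <= orf.start
                and orf.end <= big.end
                and (big.start, big.end) != (orf.start, orf.end)
            ):
                contained = True
                break
        if not contained:
            kept.append(orf)
    return kept
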