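"""Readers and writers for the external formats the pipeline consumes and
emits: FASTA (nucleotide and protein), Newick with branch lengths, GFF3 for
ORF annotations, and headered TSV tables.

Coordinates are 0-based half-open everywhere in memory and 1-based inclusive
on disk (the GFF3 convention).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .tree import PhyloTree, TreeNode

__all__ = [
    "ParseError",
    "GenomeRecord",
    "ProteinRecord",
    "LabelTable",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "write_gff3",
    "read_gff3",
    "write_tsv",
    "read_tsv",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class GenomeRecord:
    """A nucleotide genome: accession-like id, sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    meta: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A protein sequence, optionally tied to its genome and coordinates.

    ``coords`` is a ``(start, end, strand)`` tuple in 0-based half-open
    genomic coordinates, or ``None`` when the protein is a free-standing
    reference sequence.
    """

    id: str
    seq: str
    genome_id: str = ""
    coords: Optional[tuple[int, int, str]] = None


@dataclass
class LabelTable:
    """Family and in-family clade labels for reference DNAP proteins."""

    FAMILIES = ("A", "B", "C", "divA1", "divA2")

    rows: pd.DataFrame  # columns: protein_id, family, clade_label

    def __post_init__(self):
        required = {"protein_id", "family", "clade_label"}
        if not required.issubset(self.rows.columns):
            raise ParseError(f"label table needs columns {sorted(required)}")
        bad = set(self.rows["family"]) - set(self.FAMILIES)
        if bad:
            raise ParseError(f"unknown DNAP families: {sorted(bad)}")
        if self.rows["protein_id"].duplicated().any():
            raise ParseError("duplicate protein_id in label table")

    def family_of(self, protein_id: str) -> str:
        return self._map()[protein_id][0]

    def clade_of(self, protein_id: str) -> str:
        return self._map()[protein_id][1]

    def _map(self) -> dict[str, tuple[str, str]]:
        if not hasattr(self, "_cache"):
            self._cache = {
                r.protein_id: (r.family, r.clade_label)
                for r in self.rows.itertuples()
            }
        return self._cache


# ---------------------------------------------------------------------------
# FASTA

_COORD_RE = re.compile(r"loc=(\d+)\.\.(\d+)([+-])")
_GENOME_RE = re.compile(r"genome=(\S+)")


def read_fasta(path, kind: str = "nucleotide"):
    """Read a FASTA file into :class:`GenomeRecord` or :class:`ProteinRecord`.

    Sequences are upper-cased; U is mapped to T in nucleotide mode.
    Duplicate ids and empty sequences are rejected.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError("kind must be 'nucleotide' or 'protein'")
    records = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"record {i}: empty id")
        if not seq:
            raise ParseError(f"record {i} ({rec.id}): empty sequence")
        if rec.id in seen:
            raise ParseError(f"record {i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        if kind == "nucleotide":
            seq = seq.replace("U", "T")
            records.append(GenomeRecord(rec.id, seq, meta=desc))
        else:
            genome_id = ""
            coords = None
            m = _GENOME_RE.search(desc)
            if m:
                genome_id = m.group(1)
            m = _COORD_RE.search(desc)
            if m:
                start, end, strand = int(m.group(1)) - 1, int(m.group(2)), m.group(3)
                coords = (start, end, strand)
            records.append(ProteinRecord(rec.id, seq, genome_id=genome_id, coords=coords))
    return records


def write_fasta(records: Iterable[Union[GenomeRecord, ProteinRecord]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            extras = []
            if isinstance(rec, ProteinRecord):
                if rec.genome_id:
                    extras.append(f"genome={rec.genome_id}")
                if rec.coords is not None:
                    s, e, st = rec.coords
                    extras.append(f"loc={s + 1}..{e}{st}")
            elif isinstance(rec, GenomeRecord) and rec.meta:
                extras.append(rec.meta)
            header = " ".join([rec.id] + extras)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (with branch lengths) into a :class:`PhyloTree`.

    Parsing is delegated to dendropy; malformed input (e.g. unbalanced
    parentheses) raises :class:`ParseError` carrying dendropy's position
    diagnostics.
    """
    import dendropy

    text = text.strip()
    if text.count("(") != text.count(")"):
        raise ParseError(
            f"unbalanced parentheses: {text.count('(')} open vs {text.count(')')} close"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ParseError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=(dnode.taxon.label if dnode.taxon is not None else dnode.label),
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
        )
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    return tree.to_newick(precision=precision)


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(orfs, header_comment: str = "") -> str:
    """Serialize an :class:`~polswap.orf_finder.OrfSet` (or iterable of ORFs)
    as GFF3 with 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    if header_comment:
        lines.append(f"# {header_comment}")
    orf_list = getattr(orfs, "orfs", orfs)
    for i, orf in enumerate(orf_list):
        attrs = f"ID=orf{i:05d};frame={orf.frame}"
        lines.append(
            "\t".join(
                [
                    orf.genome_id,
                    "polswap",
                    "ORF",
                    str(orf.start + 1),
                    str(orf.end),
                    ".",
                    orf.strand,
                    "0",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_gff3(text: str):
    """Parse GFF3 produced by :func:`write_gff3` back into interval tuples
    ``(genome_id, start, end, strand, frame)`` with 0-based half-open
    coordinates."""
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"GFF3 line {lineno}: expected 9 columns")
        seqid, _, _, start, end, _, strand, _, attrs = fields
        m = re.search(r"frame=(\d)", attrs)
        frame = int(m.group(1)) if m else 0
        out.append((seqid, int(start) - 1, int(end), strand, frame))
    return out


# ---------------------------------------------------------------------------
# TSV


def write_tsv(table: pd.DataFrame, path=None, header_comment: str = "") -> str:
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    table.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_tsv(source) -> pd.DataFrame:
    """Read a headered TSV, skipping ``#`` comment lines."""
    if isinstance(source, (str, Path)) and "\t" not in str(source) and "\n" not in str(source):
        return pd.read_csv(source, sep="\t", comment="#")
    return pd.read_csv(io.StringIO(str(source)), sep="\t", comment="#")
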