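"""Readers and writers for the on-disk formats the pipeline touches.

Every public API in this package speaks 0-based half-open coordinates
(BED-like). Only the readers/writers in this module convert to and from
the 1-based inclusive convention of GFF3. Gzip-compressed inputs are read
transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import networkx as nx
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomicInterval",
    "ReadRecord",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "stream_fastq",
    "write_fastq",
    "write_bed",
    "read_bed",
    "write_tsv",
    "write_graphml",
]

_VALID_STRANDS = {"+", "-", "."}
_SEQ_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome/strand-aware span, 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Coordinate overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred quality scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise FormatError(f"read {self.read_id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its ordered, non-overlapping exons on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise FormatError(
                    f"gene {self.gene_id}: exon {ex} not on {self.chrom}({self.strand})"
                )
        starts = [ex.start for ex in self.exons]
        if starts != sorted(starts):
            raise FormatError(f"gene {self.gene_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons (empty for single-exon genes)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence map.

    Duplicate record names are rejected.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise FormatError(f"{path}: duplicate record name {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon features from GFF3 into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates become internal 0-based half-open
    (start - 1, end). Exons lacking a parent gene, genes without exons and
    inverted coordinates are format errors. Exons are sorted on ingest.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises several parser exception types
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc

    gene_ids = set()
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.end < gene.start:
            raise FormatError(f"{path}: gene {gene.id}: end < start")
        gene_ids.add(gene.id)
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            if exon.end < exon.start:
                raise FormatError(f"{path}: exon in {gene.id}: end < start")
            exons.append(
                GenomicInterval(exon.seqid, exon.start - 1, exon.end, gene.strand)
            )
        if not exons:
            raise FormatError(f"{path}: gene {gene.id} has no exon features")
        exons.sort(key=lambda iv: iv.start)
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(exons)))

    for exon in db.features_of_type("exon"):
        parents = [p.id for p in db.parents(exon, featuretype="gene")]
        if not parents or not set(parents) & gene_ids:
            raise FormatError(f"{path}: exon at {exon.seqid}:{exon.start} has no parent gene")
    return models


def write_gff3(path: str | Path, models: Sequence[GeneModel]) -> None:
    """Emit gene models as GFF3 (1-based inclusive on output)."""
    with _open_text(path, "wt") as out:
        out.write("##gff-version 3\n")
        for gm in models:
            span = gm.span
            out.write(
                f"{gm.chrom}\tcirclact\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            for i, ex in enumerate(gm.exons, 1):
                out.write(
                    f"{gm.chrom}\tcirclact\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{gm.strand}\t.\tID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTQ (Phred+33 only)
# ---------------------------------------------------------------------------

def stream_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ records, validating structure as we go.

    Raises :class:`FormatError` with the offending line number for
    truncated or malformed records.
    """
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header")
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise FormatError(f"{path}:{lineno}: truncated record")
            lineno += 3
            seq = seq.strip()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: sequence/quality length mismatch"
                )
            yield ReadRecord(
                read_id=header[1:].strip().split()[0],
                sequence=seq.upper(),
                qualities=tuple(ord(c) - 33 for c in qual),
            )


def write_fastq(path: str | Path, reads: Iterable[ReadRecord]) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED6 / TSV / GraphML
# ---------------------------------------------------------------------------

def write_bed(
    path: str | Path,
    rows: Iterable[tuple[GenomicInterval, str, int]],
) -> None:
    """Write (interval, name, score) triples as BED6."""
    with _open_text(path, "wt") as out:
        for interval, name, score in rows:
            out.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\t"
                f"{name}\t{score}\t{interval.strand}\n"
            )


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, int]]:
    rows = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            rows.append(
                (GenomicInterval(chrom, int(start), int(end), strand), name, int(score))
            )
    return rows


def write_tsv(path: str | Path, df) -> None:
    """Write a DataFrame as TSV without the index (stable float formatting)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_graphml(path: str | Path, graph: nx.Graph) -> None:
    nx.write_graphml(graph, path)
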