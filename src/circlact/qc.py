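"""Read preprocessing: the fixed filter stack applied to raw FASTQ.

Filters run in a fixed order — overall quality, N-base ambiguity,
adapter trimming + length, ribosomal RNA — and each read is charged to
the first filter that removes it. Every predicate is pure, so verdicts
are order-independent; only the attribution of removals depends on
order. Two instrument-level criteria sometimes listed alongside these
(signal-strength extremes, per-base error-rate proportions) describe
information that FASTQ does not carry and are out of scope here; the
Q20 rule below covers the recoverable part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._seq import revcomp
from .io_formats import ReadRecord, stream_fastq, write_fastq

FILTER_ORDER = ("low_quality", "ambiguous", "adapter_length", "rrna")


@dataclass
class QCConfig:
    quality_threshold: int = 20
    min_good_base_fraction: float = 0.50
    max_n_fraction: float = 0.05
    min_length: int = 20
    adapter_sequences: tuple[str, ...] = ()
    adapter_min_overlap: int = 8
    rrna_reference: str | Path | None = None
    rrna_kmer: int = 25

    def __post_init__(self) -> None:
        if not 0 <= self.quality_threshold <= 60:
            raise ValueError("quality_threshold out of range")
        for name in ("min_good_base_fraction", "max_n_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.rrna_kmer < 1:
            raise ValueError("rrna_kmer must be >= 1")


@dataclass
class QCReport:
    """Per-filter removal accounting; input = surviving + sum(removed)."""

    input_reads: int = 0
    surviving_reads: int = 0
    removed_by_filter: dict[str, int] = field(
        default_factory=lambda: {f: 0 for f in FILTER_ORDER}
    )

    def check(self) -> None:
        total = self.surviving_reads + sum(self.removed_by_filter.values())
        if total != self.input_reads:
            raise AssertionError(
                f"QC accounting broken: {self.input_reads} in, {total} accounted"
            )


def filter_low_quality(read: ReadRecord, config: QCConfig) -> bool:
    """Keep iff at least ``min_good_base_fraction`` of bases reach the
    Phred threshold (the removal rule is a strict 'less than')."""
    if not read.qualities:
        return False
    good = sum(q >= config.quality_threshold for q in read.qualities)
    return good / len(read.qualities) >= config.min_good_base_fraction


def filter_ambiguous(read: ReadRecord, config: QCConfig) -> bool:
    """Keep iff the N fraction does not exceed ``max_n_fraction``."""
    if not read.sequence:
        return False
    return read.sequence.count("N") / len(read.sequence) <= config.max_n_fraction


def trim_adapters(read: ReadRecord, config: QCConfig) -> ReadRecord:
    """Remove the longest 3' suffix matching a prefix of any adapter.

    Matching is exact with a minimum overlap of ``adapter_min_overlap``
    bases (a read that is entirely adapter trims to length zero).
    Trimming iterates to a fixpoint so the operation is idempotent.
    """
    seq, qual = read.sequence, read.qualities
    while True:
        best_cut = len(seq)
        for adapter in config.adapter_sequences:
            max_ov = min(len(adapter), len(seq))
            for ov in range(max_ov, config.adapter_min_overlap - 1, -1):
                if seq.endswith(adapter[:ov]):
                    best_cut = min(best_cut, len(seq) - ov)
                    break
        if best_cut == len(seq):
            break
        seq, qual = seq[:best_cut], qual[:best_cut]
    if seq is read.sequence:
        return read
    return ReadRecord(read.read_id, seq, qual)


def trim_adapters_and_filter_length(
    read: ReadRecord, config: QCConfig
) -> ReadRecord | None:
    """Adapter-trim, then drop reads shorter than ``min_length``."""
    trimmed = trim_adapters(read, config) if config.adapter_sequences else read
    if len(trimmed) < config.min_length:
        return None
    return trimmed


def build_rrna_index(sequences: Iterable[str], k: int) -> set[str]:
    """k-mer membership set over the rRNA reference, both strands."""
    index: set[str] = set()
    for seq in sequences:
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                index.add(strand_seq[i : i + k])
    return index


def filter_rrna(read: ReadRecord, config: QCConfig, rrna_index: set[str]) -> bool:
    """Keep iff no read k-mer occurs in the rRNA k-mer set."""
    k = config.rrna_kmer
    seq = read.sequence
    return not any(seq[i : i + k] in rrna_index for i in range(len(seq) - k + 1))


def qc_read(
    read: ReadRecord, config: QCConfig, rrna_index: set[str] | None
) -> tuple[ReadRecord | None, str | None]:
    """Run the full stack on one read: (surviving read, removing filter)."""
    if not filter_low_quality(read, config):
        return None, "low_quality"
    if not filter_ambiguous(read, config):
        return None, "ambiguous"
    trimmed = trim_adapters_and_filter_length(read, config)
    if trimmed is None:
        return None, "adapter_length"
    if rrna_index is not None and not filter_rrna(trimmed, config, rrna_index):
        return None, "rrna"
    return trimmed, None


def run_qc(
    reads: Iterable[ReadRecord],
    config: QCConfig,
    rrna_index: set[str] | None = None,
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the filter stack; returns surviving reads and the report."""
    if rrna_index is None and config.rrna_reference is not None:
        from .io_formats import read_fasta

        rrna_index = build_rrna_index(
            read_fasta(config.rrna_reference).values(), config.rrna_kmer
        )
    report = QCReport()
    survivors: list[ReadRecord] = []
    for read in reads:
        report.input_reads += 1
        kept, reason = qc_read(read, config, rrna_index)
        if kept is None:
            report.removed_by_filter[reason] += 1
        else:
            survivors.append(kept)
            report.surviving_reads += 1
    report.check()
    return survivors, report


def run_qc_file(
    fastq_in: str | Path, fastq_out: str | Path, config: QCConfig
) -> QCReport:
    survivors, report = run_qc(stream_fastq(fastq_in), config)
    write_fastq(fastq_out, survivors)
    return report
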