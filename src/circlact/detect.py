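"""Back-splice junction detection by reversed-order terminal anchors.

A linear read maps colinearly: its first bases sit upstream of its last
bases. A read crossing a back-splice junction maps the other way round —
the read's 5' anchor comes from the *end* of the circle and its 3'
anchor from the *start*. The detector takes the terminal ``anchor_length``
bases of each read, places both anchors by exact match, and calls a
candidate when they map uniquely to one chromosome in reversed genomic
order within ``max_span``, with the breakpoint extended so that read and
genome stay contiguous and the flanks spell the canonical GT-AG
donor/acceptor signal on the circle's strand. Minus-strand circles are
found by rerunning the procedure on the reverse-complemented read;
coordinates are always reported on the forward reference.

Anchors are exact-match only: this is a deterministic desk-scale
detector for error-free reads, not a mismatch-tolerant aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._seq import revcomp
from .io_formats import GenomicInterval, ReadRecord

__all__ = [
    "DetectorConfig",
    "CircCall",
    "DetectionReport",
    "build_anchor_index",
    "detect_backsplice",
    "call_circrnas",
]


@dataclass
class DetectorConfig:
    anchor_length: int = 20
    max_span: int = 100_000
    min_junction_reads: int = 2
    allowed_signals: frozenset[str] = frozenset({"GT-AG"})

    def __post_init__(self) -> None:
        if self.anchor_length < 10:
            raise ValueError("anchor_length must be >= 10")
        if self.max_span <= 0:
            raise ValueError("max_span must be > 0")
        if self.min_junction_reads < 1:
            raise ValueError("min_junction_reads must be >= 1")


@dataclass
class CircCall:
    """One back-splice junction with its supporting evidence."""

    circ_id: str
    interval: GenomicInterval
    junction_reads: int
    splice_signal: str
    breakpoint_reads: list[str]
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class DetectionReport:
    reads_seen: int = 0
    ambiguous_anchor: int = 0
    candidates: int = 0
    below_threshold: int = 0
    disallowed_signal: int = 0


AnchorIndex = dict[str, list[tuple[str, int]]]


def build_anchor_index(genome: Mapping[str, str], anchor_length: int) -> AnchorIndex:
    """Map every forward-strand genomic k-mer to its (chrom, pos) list.

    k-mers never cross chromosome boundaries. Callers query reverse
    complements themselves.
    """
    if any(anchor_length > len(seq) for seq in genome.values()):
        raise ValueError("anchor_length exceeds a chromosome length")
    index: AnchorIndex = defaultdict(list)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i in range(len(seq) - anchor_length + 1):
            index[seq[i : i + anchor_length]].append((chrom, i))
    return dict(index)


def _signal_flanks(strand: str) -> tuple[str, str]:
    # forward-reference flanks consistent with sense-strand GT-AG
    return ("AG", "GT") if strand == "+" else ("AC", "CT")


def _scan_orientation(
    seq: str,
    strand: str,
    index: AnchorIndex,
    genome: Mapping[str, str],
    config: DetectorConfig,
) -> tuple[GenomicInterval | None, bool]:
    """One orientation of the anchor test.

    Returns (candidate interval or None, anchors_ambiguous).
    """
    k = config.anchor_length
    a5, a3 = seq[:k], seq[-k:]
    hits5 = index.get(a5, [])
    hits3 = index.get(a3, [])
    if len(hits5) > 1 or len(hits3) > 1:
        return None, True
    if not hits5 or not hits3:
        return None, False
    (chrom5, p5), (chrom3, p3) = hits5[0], hits3[0]
    if chrom5 != chrom3 or p3 >= p5:
        return None, False  # colinear or cross-chromosome

    chrom_seq = genome[chrom5]
    L = len(seq)
    # maximal prefix of the read contiguous with the genome from p5:
    # seq[:e] == chrom[p5 : p5+e]
    e = k
    while e < L and p5 + e < len(chrom_seq) and seq[e] == chrom_seq[p5 + e]:
        e += 1
    # maximal suffix contiguous with the genome ending at p3+k:
    # seq[L-s:] == chrom[p3+k-s : p3+k]
    s = k
    while s < L and p3 + k - s - 1 >= 0 and \
            seq[L - s - 1] == chrom_seq[p3 + k - s - 1]:
        s += 1
    # breakpoint offset b splits the read into circle-end part read[:b]
    # (at p5) and circle-start part read[b:] (ending at p3+k); contiguity
    # requires L - s <= b <= e. The circle interval is then
    # [p3 + k - (L - b), p5 + b). Pick the leftmost b whose flanks spell
    # the canonical signal.
    left, right = _signal_flanks(strand)
    for b in range(max(L - s, 1), min(e, L - 1) + 1):
        start = p3 + k - (L - b)
        end = p5 + b
        if start >= end or end - start > config.max_span:
            continue
        if start < 2 or end + 2 > len(chrom_seq):
            continue
        if chrom_seq[start - 2 : start] == left and \
                chrom_seq[end : end + 2] == right:
            return GenomicInterval(chrom5, start, end, strand), False
    return None, False


def detect_backsplice(
    read: ReadRecord,
    index: AnchorIndex,
    genome: Mapping[str, str],
    config: DetectorConfig,
) -> tuple[GenomicInterval | None, bool]:
    """Back-splice candidate for one read, or None.

    The plus orientation is tried first, then the reverse complement
    (minus-strand circle). Returns (interval, ambiguous_flag).
    """
    if len(read) < 2 * config.anchor_length:
        return None, False
    cand, amb = _scan_orientation(read.sequence, "+", index, genome, config)
    if cand is not None:
        return cand, False
    cand2, amb2 = _scan_orientation(revcomp(read.sequence), "-", index, genome, config)
    if cand2 is not None:
        return cand2, False
    return None, amb or amb2


def _signal_of(interval: GenomicInterval, genome: Mapping[str, str]) -> str:
    seq = genome[interval.chrom]
    left = seq[interval.start - 2 : interval.start]
    right = seq[interval.end : interval.end + 2]
    if interval.strand == "+":
        donor, acceptor = right, left
    else:
        donor, acceptor = revcomp(left), revcomp(right)
    return f"{donor}-{acceptor}"


def call_circrnas(
    reads: Iterable[ReadRecord] | Mapping[str, Iterable[ReadRecord]],
    index: AnchorIndex,
    genome: Mapping[str, str],
    config: DetectorConfig | None = None,
) -> tuple[list[CircCall], DetectionReport]:
    """Aggregate per-read candidates into junction calls.

    ``reads`` may be a flat iterable or a sample -> reads mapping; in the
    latter case per-sample support is kept on each call. Calls require
    ``min_junction_reads`` support and an allowed splice signal, and are
    emitted in deterministic (chrom, start, end, strand) order with ids
    ``circ_00001`` onward.
    """
    config = config or DetectorConfig()
    if isinstance(reads, Mapping):
        stream = ((sample, r) for sample, rs in reads.items() for r in rs)
    else:
        stream = (("all", r) for r in reads)

    report = DetectionReport()
    support: dict[GenomicInterval, list[str]] = defaultdict(list)
    per_sample: dict[GenomicInterval, dict[str, int]] = defaultdict(dict)
    for sample, read in stream:
        report.reads_seen += 1
        cand, ambiguous = detect_backsplice(read, index, genome, config)
        if ambiguous:
            report.ambiguous_anchor += 1
            continue
        if cand is None:
            continue
        report.candidates += 1
        support[cand].append(read.read_id)
        per_sample[cand][sample] = per_sample[cand].get(sample, 0) + 1

    calls: list[CircCall] = []
    n = 0
    for iv in sorted(support, key=lambda v: (v.chrom, v.start, v.end, v.strand)):
        read_ids = support[iv]
        if len(read_ids) < config.min_junction_reads:
            report.below_threshold += 1
            continue
        signal = _signal_of(iv, genome)
        if signal not in config.allowed_signals:
            report.disallowed_signal += 1
            continue
        n += 1
        calls.append(
            CircCall(
                circ_id=f"circ_{n:05d}",
                interval=iv,
                junction_reads=len(read_ids),
                splice_signal=signal,
                breakpoint_reads=sorted(read_ids),
                sample_counts=dict(sorted(per_sample[iv].items())),
            )
        )
    return calls, report
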