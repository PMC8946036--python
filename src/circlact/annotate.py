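"""Five-way circRNA source classification and characterization summaries.

A call is classified against gene models on its own strand first:
a span inside the exon union of one sense gene is exonic (EciRNA); a
span entirely inside one intron is intronic (IciRNA); any other sense
overlap — mixed exon/intron content or a span sticking out of the gene —
is exon–intron (EIciRNA, "sense-overlapping"). Calls with no sense
overlap are antisense if an opposite-strand gene overlaps, otherwise
intergenic. Classification is span-based: the internal splicing of the
mature circle is unknown from a junction call, so "exon-derived" is
judged on genomic extent.

When a span overlaps several sense genes, the gene with the largest
overlap wins (ties: smaller gene start).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .detect import CircCall
from .io_formats import GeneModel, GenomicInterval

CATEGORY_ORDER = ("EciRNA", "IciRNA", "EIciRNA", "antisense", "intergenic")

LENGTH_BIN_EDGES = (200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000)
GC_BIN_EDGES = (0.30, 0.40, 0.50, 0.60, 0.70, 0.80)


@dataclass(frozen=True)
class CircAnnotation:
    circ_id: str
    category: str
    parent_gene: str | None
    exon_count: int
    length: int
    gc_fraction: float | None
    chromosome: str


@dataclass
class CharacterizationSummary:
    """The per-cohort characterization tables (counts, not figures)."""

    n_circrnas: int
    per_chromosome: dict[str, int]
    length_histogram: dict[str, int]
    exon_count_histogram: dict[int, int]
    gc_histogram: dict[str, int]
    category_counts: dict[str, int]
    category_percentages: dict[str, float]
    splice_signal_tally: dict[str, int]
    mean_length: float | None


class GeneIndex:
    """Interval lookup of gene models, split by strand."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for gm in models:
            span = gm.span
            self._trees[(gm.chrom, gm.strand)][span.start : span.end] = gm

    def overlapping(self, iv: GenomicInterval, strand: str) -> list[GeneModel]:
        tree = self._trees.get((iv.chrom, strand))
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda gm: gm.span.start)


def gc_fraction(sequence: str) -> float | None:
    """(#G + #C) / (#non-N bases); None when no informative base exists."""
    if not sequence:
        raise ValueError("empty sequence")
    informative = len(sequence) - sequence.count("N")
    if informative == 0:
        return None
    return (sequence.count("G") + sequence.count("C")) / informative


def _covered_by_exons(iv: GenomicInterval, gene: GeneModel) -> bool:
    """True iff every base of the span lies inside the gene's exons."""
    pos = iv.start
    for ex in gene.exons:
        if ex.end <= pos:
            continue
        if ex.start > pos:
            return False
        pos = min(ex.end, iv.end)
        if pos >= iv.end:
            return True
    return pos >= iv.end


def _in_one_intron(iv: GenomicInterval, gene: GeneModel) -> bool:
    return any(
        intr.start <= iv.start and iv.end <= intr.end for intr in gene.introns()
    )


def classify_circ(
    call: CircCall,
    index: GeneIndex,
    genome: Mapping[str, str] | None = None,
) -> CircAnnotation:
    """Assign exactly one of the five source categories to a call."""
    iv = call.interval
    opposite = "-" if iv.strand == "+" else "+"
    sense = index.overlapping(iv, iv.strand)
    if sense:
        gene = max(
            sense,
            key=lambda gm: (iv.overlap_length(gm.span), -gm.span.start),
        )
        if _covered_by_exons(iv, gene):
            category = "EciRNA"
        elif _in_one_intron(iv, gene):
            category = "IciRNA"
        else:
            category = "EIciRNA"
        parent = gene.gene_id
        exon_count = sum(1 for ex in gene.exons if ex.overlap_length(iv) > 0)
    elif index.overlapping(iv, opposite):
        category, parent, exon_count = "antisense", None, 0
    else:
        category, parent, exon_count = "intergenic", None, 0

    gc = None
    if genome is not None and iv.chrom in genome:
        seq = genome[iv.chrom][iv.start : iv.end]
        gc = gc_fraction(seq)
    return CircAnnotation(
        circ_id=call.circ_id,
        category=category,
        parent_gene=parent,
        exon_count=exon_count,
        length=len(iv),
        gc_fraction=gc,
        chromosome=iv.chrom,
    )


def annotate_calls(
    calls: Sequence[CircCall],
    models: Sequence[GeneModel],
    genome: Mapping[str, str] | None = None,
) -> list[CircAnnotation]:
    index = GeneIndex(models)
    return [classify_circ(call, index, genome) for call in calls]


def _length_bin(length: int) -> str:
    prev = 0
    for edge in LENGTH_BIN_EDGES:
        if length <= edge:
            return f"{prev + 1}-{edge}" if prev else f"<={edge}"
        prev = edge
    return f">{LENGTH_BIN_EDGES[-1]}"


def _gc_bin(gc: float) -> str:
    if gc < GC_BIN_EDGES[0]:
        return f"<{GC_BIN_EDGES[0]:.0%}"
    for lo, hi in zip(GC_BIN_EDGES, GC_BIN_EDGES[1:]):
        if gc < hi:
            return f"{lo:.0%}-{hi:.0%}"
    return f">={GC_BIN_EDGES[-1]:.0%}"


def summarize(
    annotations: Sequence[CircAnnotation],
    calls: Sequence[CircCall],
) -> CharacterizationSummary:
    """All characterization tables; totals conserve the input count."""
    n = len(annotations)
    lengths = [a.length for a in annotations]
    cat_counts = Counter(a.category for a in annotations)
    category_counts = {c: cat_counts.get(c, 0) for c in CATEGORY_ORDER}
    percentages = {
        c: (100.0 * v / n if n else 0.0) for c, v in category_counts.items()
    }
    gc_hist: Counter = Counter()
    for a in annotations:
        if a.gc_fraction is not None:
            gc_hist[_gc_bin(a.gc_fraction)] += 1
    return CharacterizationSummary(
        n_circrnas=n,
        per_chromosome=dict(sorted(Counter(a.chromosome for a in annotations).items())),
        length_histogram=dict(Counter(_length_bin(l) for l in lengths)),
        exon_count_histogram=dict(sorted(Counter(a.exon_count for a in annotations).items())),
        gc_histogram=dict(gc_hist),
        category_counts=category_counts,
        category_percentages=percentages,
        splice_signal_tally=dict(sorted(Counter(c.splice_signal for c in calls).items())),
        mean_length=float(np.mean(lengths)) if lengths else None,
    )
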