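"""Synthetic circRNA study generator with machine-readable ground truth.

Everything downstream of raw sequencing is testable against a fully
specified simulated study: a small multi-chromosome genome with gene
models on both strands, back-splice circRNAs planted in all five source
categories (exonic, intronic, exon–intron, antisense, intergenic) with
canonical GT-AG flanks, junction-spanning reads, per-sample negative
binomial junction counts with planted two-group differential expression,
and miRNA seed sites written into circRNA/mRNA sequences at known
multiplicities.

Determinism contract: the same :class:`SyntheticConfig` (including seed)
produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import count_occurrences, revcomp
from .io_formats import (
    GeneModel,
    GenomicInterval,
    ReadRecord,
    write_fasta,
    write_fastq,
    write_gff3,
    write_tsv,
)

CATEGORIES = ("EciRNA", "IciRNA", "EIciRNA", "antisense", "intergenic")

GROUP_A = "non_lactation"
GROUP_B = "early_lactation"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """The generator could not satisfy the requested configuration."""


@dataclass
class SyntheticConfig:
    """All knobs of the simulated study.

    Defaults describe a desk-scale study: 3 chromosomes, 12 genes, 50
    planted circles (10 per category) spanning 48–5,000 bp, two groups of
    3 samples with NB counts at dispersion 0.1, and 20 miRNAs with
    distinct 7-mer seeds.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 120_000
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (3, 5)
    n_circ_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CATEGORIES}
    )
    circ_length_range: tuple[int, int] = (48, 5_000)
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.1
    de_fraction: float = 0.2
    de_log2fc: float = 2.0
    n_mirnas: int = 20
    n_mrnas: int = 15
    mre_multiplicity_range: tuple[int, int] = (1, 4)
    read_length: int = 50
    junction_reads_per_circ: tuple[int, int] = (3, 8)
    n_background_reads: int = 300
    anchor_margin: int = 20  # min junction-read overhang on each side
    mirna_length: int = 22
    mean_count_range: tuple[float, float] = (20.0, 500.0)
    n_terms: int = 8

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_samples_per_group",
                     "n_mirnas", "n_mrnas", "read_length", "mirna_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        lo, hi = self.circ_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid circ_length_range")
        if hi >= self.chrom_length:
            raise ValueError("circ_length_range must fit within chrom_length")
        unknown = set(self.n_circ_per_category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown circRNA categories: {sorted(unknown)}")
        if any(v < 0 for v in self.n_circ_per_category.values()):
            raise ValueError("n_circ_per_category values must be >= 0")
        if self.read_length < 2 * self.anchor_margin:
            raise ValueError("read_length must be >= 2 * anchor_margin")


@dataclass(frozen=True)
class PlantedCircle:
    circ_id: str
    interval: GenomicInterval
    category: str
    splice_signal: str = "GT-AG"

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class GroundTruth:
    """Machine-readable truth tables for every planted object."""

    circles: list[PlantedCircle]
    de_labels: pd.DataFrame  # circ_id, true_log2fc, label
    mres: pd.DataFrame  # rna_id, rna_class, mirna_id, count, positions
    groups: dict[str, str]  # sample_id -> group
    size_factors: pd.Series  # true per-sample scaling


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth: GroundTruth
    reads: list[ReadRecord]
    counts: pd.DataFrame  # circ_id x sample_id junction counts
    mirnas: dict[str, str]
    circ_seqs: dict[str, str]
    mrna_seqs: dict[str, str]
    gene_terms: pd.DataFrame  # term_id, gene_id


# ---------------------------------------------------------------------------
# genome + gene models
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """Random genome plus non-overlapping gene models on both strands.

    Genes are laid out left to right with wide intergenic gaps (room for
    intergenic circles); strands alternate so both are represented.
    Raises :class:`GenerationError` when a chromosome cannot hold its
    share of gene models.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: bytearray(_random_bases(rng, config.chrom_length).encode())
              for c in chrom_names}

    models: list[GeneModel] = []
    lo_ex, hi_ex = config.exons_per_gene
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gene_no = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        cursor = int(rng.integers(6_000, 9_000))
        for _ in range(n_here):
            gene_no += 1
            n_exons = int(rng.integers(lo_ex, hi_ex + 1))
            exon_lens = rng.integers(150, 401, size=n_exons)
            intron_lens = rng.integers(600, 2_501, size=max(0, n_exons - 1))
            strand = "+" if gene_no % 2 else "-"
            exons, pos = [], cursor
            for k in range(n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            if pos + 2 > config.chrom_length:
                raise GenerationError(
                    f"chromosome {chrom} too short for requested gene models"
                )
            models.append(GeneModel(f"gene_{gene_no:03d}", chrom, strand, tuple(exons)))
            cursor = pos + int(rng.integers(6_000, 9_000))
    return genome, models


# ---------------------------------------------------------------------------
# circle planting
# ---------------------------------------------------------------------------

def _flanks_for_strand(strand: str) -> tuple[str, str]:
    # Sense-strand GT-AG: forward-strand flanks are AG|circle|GT on '+',
    # AC|circle|CT on '-' (the reverse complement pair).
    return ("AG", "GT") if strand == "+" else ("AC", "CT")


def _write_flanks(genome: dict[str, bytearray], iv: GenomicInterval) -> None:
    left, right = _flanks_for_strand(iv.strand)
    genome[iv.chrom][iv.start - 2 : iv.start] = left.encode()
    genome[iv.chrom][iv.end : iv.end + 2] = right.encode()


def plant_circles(
    config: SyntheticConfig,
    genome: dict[str, bytearray],
    models: list[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[PlantedCircle]:
    """Place circles of every requested category and write their flanks.

    The genome is mutated in place: the two bases on each side of a
    planted span become the canonical back-splice signal on the circle's
    strand. Spans (padded by 30 bp) never overlap each other, so each
    junction is unambiguous.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo_len, hi_len = config.circ_length_range
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}

    def is_free(chrom: str, start: int, end: int) -> bool:
        pad = 30
        return all(
            end + pad <= s or e + pad <= start for s, e in occupied[chrom]
        )

    def claim(iv: GenomicInterval) -> None:
        occupied[iv.chrom].append((iv.start, iv.end))

    # candidate site pools per category
    sense_exons = [
        (gm, ex) for gm in models for ex in gm.exons if len(ex) >= lo_len + 4
    ]
    introns = [
        (gm, iv) for gm in models for iv in gm.introns() if len(iv) >= lo_len + 8
    ]
    exon_pairs = [
        (gm, a, b) for gm in models for a, b in zip(gm.exons, gm.exons[1:])
        if len(a) >= 20 and len(b) >= 20
    ]
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in genome}
    for gm in models:
        by_chrom[gm.chrom].append(gm)
    for chrom, gms in by_chrom.items():
        gms = sorted(gms, key=lambda g: g.span.start)
        edges = [100] + [g.span.end + 100 for g in gms]
        ends = [g.span.start - 100 for g in gms] + [config.chrom_length - 100]
        for s, e in zip(edges, ends):
            if e - s >= lo_len + 8:
                gaps.append((chrom, s, e))

    def place(category: str) -> GenomicInterval:
        for _ in range(400):
            if category == "EciRNA":
                if not sense_exons:
                    break
                gm, ex = sense_exons[rng.integers(len(sense_exons))]
                max_len = min(hi_len, len(ex))
                length = int(rng.integers(lo_len, max_len + 1))
                start = int(rng.integers(ex.start, ex.end - length + 1))
                iv = GenomicInterval(ex.chrom, start, start + length, gm.strand)
            elif category == "IciRNA":
                if not introns:
                    break
                gm, intr = introns[rng.integers(len(introns))]
                max_len = min(hi_len, len(intr) - 6)
                length = int(rng.integers(lo_len, max_len + 1))
                start = int(rng.integers(intr.start + 3, intr.end - 3 - length + 1))
                iv = GenomicInterval(intr.chrom, start, start + length, gm.strand)
            elif category == "EIciRNA":
                if not exon_pairs:
                    break
                gm, a, b = exon_pairs[rng.integers(len(exon_pairs))]
                start = int(rng.integers(a.start + 2, a.end - 2))
                end = int(rng.integers(b.start + 2, b.end - 2))
                if not lo_len <= end - start <= hi_len:
                    continue
                iv = GenomicInterval(a.chrom, start, end, gm.strand)
            elif category == "antisense":
                if not models:
                    break
                gm = models[rng.integers(len(models))]
                span = gm.span
                max_len = min(hi_len, len(span))
                if max_len < lo_len:
                    continue
                length = int(rng.integers(lo_len, max_len + 1))
                start = int(rng.integers(span.start, span.end - length + 1))
                iv = GenomicInterval(span.chrom, start, start + length,
                                     "-" if gm.strand == "+" else "+")
            else:  # intergenic
                if not gaps:
                    break
                chrom, s, e = gaps[rng.integers(len(gaps))]
                max_len = min(hi_len, e - s - 6)
                length = int(rng.integers(lo_len, max_len + 1))
                start = int(rng.integers(s + 3, e - 3 - length + 1))
                strand = "+" if rng.integers(2) else "-"
                iv = GenomicInterval(chrom, start, start + length, strand)
            if iv.start >= 2 and iv.end + 2 <= config.chrom_length and \
                    is_free(iv.chrom, iv.start, iv.end):
                return iv
        raise GenerationError(f"cannot place a circle of category {category}")

    placed: list[tuple[GenomicInterval, str]] = []
    for category in CATEGORIES:
        for _ in range(config.n_circ_per_category.get(category, 0)):
            iv = place(category)
            claim(iv)
            placed.append((iv, category))

    placed.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    circles = []
    for i, (iv, category) in enumerate(placed, 1):
        _write_flanks(genome, iv)
        circles.append(PlantedCircle(f"circ_{i:04d}", iv, category))
    return circles


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SyntheticConfig,
    circles: list[PlantedCircle],
    genome: dict[str, bytearray] | dict[str, str],
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Junction-spanning reads for every circle plus colinear background.

    A junction read is the circle's 3' end concatenated to its 5' start,
    with the breakpoint uniformly placed at least ``anchor_margin`` bases
    from either read end; minus-strand circles emit the reverse
    complement. Background reads are plain genome fragments on either
    strand. All reads carry Q40 qualities (no error model).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.read_length
    margin = config.anchor_margin
    if L < 2 * margin:
        raise ValueError("read_length must be >= 2 * anchor_margin")
    seqs = {c: (s.decode() if isinstance(s, (bytes, bytearray)) else s)
            for c, s in genome.items()}

    reads: list[ReadRecord] = []
    q40 = tuple([40] * L)
    lo_r, hi_r = config.junction_reads_per_circ
    for circ in circles:
        iv = circ.interval
        if len(iv) <= L - margin:
            raise GenerationError(
                f"{circ.circ_id}: circle length {len(iv)} too short to show "
                f"split anchors at read length {L}"
            )
        n_reads = int(rng.integers(lo_r, hi_r + 1))
        chrom_seq = seqs[iv.chrom]
        for k in range(n_reads):
            b = int(rng.integers(margin, L - margin + 1))
            b = min(b, len(iv))
            head = chrom_seq[iv.end - b : iv.end]
            tail = chrom_seq[iv.start : iv.start + L - b]
            seq = head + tail
            if iv.strand == "-":
                seq = revcomp(seq)
            reads.append(ReadRecord(f"{circ.circ_id}|j{k + 1}", seq, q40))

    chrom_names = sorted(seqs)
    for k in range(config.n_background_reads):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        pos = int(rng.integers(0, len(seqs[chrom]) - L + 1))
        seq = seqs[chrom][pos : pos + L]
        if rng.integers(2):
            seq = revcomp(seq)
        reads.append(ReadRecord(f"bg_{k + 1:05d}", seq, q40))
    return reads


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) draws; dispersion 0 degenerates to Poisson."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SyntheticConfig,
    circles: list[PlantedCircle],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], pd.Series]:
    """Per-sample NB junction counts with planted differential expression.

    Baseline means are log-uniform over ``mean_count_range``; a fraction
    ``de_fraction`` of circles get the group-B mean multiplied by
    ``2**±de_log2fc`` (half up, half down). True per-sample size factors
    perturb library depth. Returns (counts, de_labels, groups,
    size_factors); the log2 fold change convention is group B
    (early lactation) relative to group A (non-lactation).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = len(circles)
    ids = [c.circ_id for c in circles]
    samples_a = [f"{GROUP_A}_{i + 1}" for i in range(config.n_samples_per_group)]
    samples_b = [f"{GROUP_B}_{i + 1}" for i in range(config.n_samples_per_group)]
    groups = {s: GROUP_A for s in samples_a} | {s: GROUP_B for s in samples_b}

    log_lo, log_hi = np.log(config.mean_count_range)
    base_mu = np.exp(rng.uniform(log_lo, log_hi, size=n))
    lfc = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    half = n_de // 2
    lfc[de_idx[:half]] = -config.de_log2fc
    lfc[de_idx[half:]] = config.de_log2fc

    sf = pd.Series(
        2.0 ** rng.uniform(-0.5, 0.5, size=len(groups)),
        index=samples_a + samples_b,
        name="size_factor",
    )
    counts = np.zeros((n, len(sf)), dtype=int)
    for j, sample in enumerate(sf.index):
        mu = base_mu * (2.0 ** lfc if groups[sample] == GROUP_B else 1.0)
        counts[:, j] = nb_draw(rng, mu * sf.iloc[j], config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="circ_id"),
                             columns=sf.index)
    labels = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "null"))
    de_df = pd.DataFrame(
        {"circ_id": ids, "true_log2fc": lfc, "label": labels}
    )
    return counts_df, de_df, groups, sf


# ---------------------------------------------------------------------------
# miRNA seed sites
# ---------------------------------------------------------------------------

SEED_START, SEED_END = 1, 8  # miRNA positions 2-8, 0-based half-open


def mirna_seed(mirna_seq: str, span: tuple[int, int] = (SEED_START, SEED_END)) -> str:
    s, e = span
    if len(mirna_seq) < e:
        raise ValueError(f"miRNA of length {len(mirna_seq)} shorter than seed span")
    return mirna_seq[s:e]


def generate_mirnas(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """miRNA sequences with pairwise-distinct seed regions."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mirnas: dict[str, str] = {}
    seeds: set[str] = set()
    for i in range(config.n_mirnas):
        for _ in range(1000):
            seq = _random_bases(rng, config.mirna_length)
            if mirna_seed(seq) not in seeds:
                seeds.add(mirna_seed(seq))
                mirnas[f"miR_{i + 1:03d}"] = seq
                break
        else:  # pragma: no cover
            raise GenerationError("could not draw distinct miRNA seeds")
    return mirnas


def _plant_sites_in_sequence(
    rng: np.random.Generator,
    length: int,
    sites: list[tuple[str, str]],  # (mirna_id, site 7-mer)
    forbidden: dict[str, str],  # mirna_id -> site 7-mer, must not occur elsewhere
) -> tuple[str, dict[str, list[int]]]:
    """Random sequence of ``length`` containing exactly the given sites.

    Sites are placed non-overlapping with >= site-length gaps; any
    accidental occurrence of a forbidden 7-mer necessarily touches a gap
    base, which is resampled until the sequence is clean, so truth counts
    stay exact.
    """
    k = 7
    n_sites = len(sites)
    min_len = k * n_sites + k * (n_sites + 1)
    if length < min_len:
        raise GenerationError(
            f"sequence of length {length} too short for {n_sites} sites"
        )
    order = list(rng.permutation(n_sites)) if n_sites else []
    extra = length - min_len
    gaps = rng.multinomial(extra, [1.0 / (n_sites + 1)] * (n_sites + 1)) + k

    parts: list[str] = []
    positions: dict[str, list[int]] = {}
    pos = 0
    site_spans: list[tuple[int, int]] = []
    for idx in range(n_sites):
        parts.append(_random_bases(rng, int(gaps[idx])))
        pos += int(gaps[idx])
        mirna_id, site = sites[order[idx]]
        parts.append(site)
        positions.setdefault(mirna_id, []).append(pos)
        site_spans.append((pos, pos + k))
        pos += k
    parts.append(_random_bases(rng, int(gaps[-1])))
    seq = bytearray("".join(parts).encode())

    in_site = np.zeros(length, dtype=bool)
    for s, e in site_spans:
        in_site[s:e] = True
    planted_at = {m: set(p) for m, p in positions.items()}

    for _ in range(2000):
        dirty = []
        text = seq.decode()
        for mirna_id, site in forbidden.items():
            want = planted_at.get(mirna_id, set())
            i = text.find(site)
            while i != -1:
                if i not in want:
                    dirty.append(i)
                i = text.find(site, i + 1)
        if not dirty:
            break
        for i in dirty:
            free = [p for p in range(i, i + k) if not in_site[p]]
            p = free[int(rng.integers(len(free)))]
            seq[p] = int(rng.choice(_BASES))
    else:  # pragma: no cover
        raise GenerationError("could not scrub accidental seed sites")

    for m, plist in positions.items():
        plist.sort()
    return seq.decode(), positions


def plant_mres(
    config: SyntheticConfig,
    circles: list[PlantedCircle],
    rng: np.random.Generator | None = None,
    mirnas: dict[str, str] | None = None,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], pd.DataFrame]:
    """circRNA and mRNA sequences with seed sites at known multiplicities.

    Returns (mirnas, circ_seqs, mrna_seqs, truth) where truth has columns
    rna_id, rna_class, mirna_id, count, positions. A site is the exact
    reverse complement of the miRNA seed (positions 2-8); no other
    occurrence of any planted miRNA's seed complement exists anywhere in
    the emitted sequences.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if mirnas is None:
        mirnas = generate_mirnas(config, rng)
    seeds = {m: mirna_seed(s) for m, s in mirnas.items()}
    if len(set(seeds.values())) != len(seeds):
        raise ValueError("miRNAs with identical seed regions are not allowed")
    site_of = {m: revcomp(seed) for m, seed in seeds.items()}

    lo_m, hi_m = config.mre_multiplicity_range
    rows = []

    def build(rna_id: str, rna_class: str, length: int) -> str:
        # n sites need 7n site bases plus >= 7 bases in each of the n+1 gaps
        capacity = max(0, (length - 7) // 14)
        n_targeting = int(rng.integers(3, min(9, len(mirnas)) + 1))
        chosen = rng.choice(sorted(mirnas), size=n_targeting, replace=False)
        sites: list[tuple[str, str]] = []
        mult: dict[str, int] = {}
        total = 0
        for m in chosen:
            k = min(int(rng.integers(lo_m, hi_m + 1)), capacity - total)
            if k <= 0:
                continue
            total += k
            mult[m] = k
            sites.extend([(m, site_of[m])] * k)
        seq, positions = _plant_sites_in_sequence(rng, length, sites, site_of)
        for m in sorted(mult):
            rows.append(
                {
                    "rna_id": rna_id,
                    "rna_class": rna_class,
                    "mirna_id": m,
                    "count": mult[m],
                    "positions": ",".join(map(str, positions[m])),
                }
            )
        return seq

    circ_seqs: dict[str, str] = {}
    for circ in circles:
        length = max(len(circ.interval), 200)
        circ_seqs[circ.circ_id] = build(circ.circ_id, "circRNA", length)
    mrna_seqs: dict[str, str] = {}
    for i in range(config.n_mrnas):
        rna_id = f"mRNA_{i + 1:03d}"
        mrna_seqs[rna_id] = build(rna_id, "mRNA", int(rng.integers(500, 1501)))

    truth = pd.DataFrame(rows, columns=["rna_id", "rna_class", "mirna_id",
                                        "count", "positions"])
    return mirnas, circ_seqs, mrna_seqs, truth


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

def _gene_terms(
    config: SyntheticConfig, models: list[GeneModel], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    genes = [gm.gene_id for gm in models]
    for t in range(config.n_terms):
        size = int(rng.integers(2, max(3, len(genes) // 2) + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        for g in sorted(members):
            rows.append({"term_id": f"term_{t + 1:02d}", "gene_id": g})
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])


def generate_study(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> SyntheticStudy:
    """Run every generator stage off one seeded RNG; optionally write all
    study files (FASTA/GFF3/FASTQ/TSV truth tables) under ``outdir``."""
    rng = np.random.default_rng(config.seed)
    genome_raw, models = generate_genome(config, rng)
    circles = plant_circles(config, genome_raw, models, rng)
    genome = {c: s.decode() for c, s in genome_raw.items()}
    reads = simulate_reads(config, circles, genome, rng)
    counts, de_df, groups, sf = simulate_counts(config, circles, rng)
    mirnas, circ_seqs, mrna_seqs, mre_truth = plant_mres(config, circles, rng)
    terms = _gene_terms(config, models, rng)

    truth = GroundTruth(circles, de_df, mre_truth, groups, sf)
    study = SyntheticStudy(
        config=config, genome=genome, models=models, truth=truth, reads=reads,
        counts=counts, mirnas=mirnas, circ_seqs=circ_seqs, mrna_seqs=mrna_seqs,
        gene_terms=terms,
    )
    if outdir is not None:
        write_study(study, outdir)
    return study


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study artifact; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fa"), ("annotation", "genes.gff3"),
        ("reads", "reads.fastq"), ("counts", "counts.tsv"),
        ("groups", "groups.tsv"), ("mirnas", "mirnas.fa"),
        ("circ_seqs", "circ_seqs.fa"), ("mrna_seqs", "mrna_seqs.fa"),
        ("truth_circles", "truth_circles.tsv"), ("truth_de", "truth_de.tsv"),
        ("truth_mres", "truth_mres.tsv"), ("gene_terms", "gene_terms.tsv"),
        ("size_factors", "truth_size_factors.tsv"),
    ]}
    write_fasta(paths["genome"], study.genome)
    write_gff3(paths["annotation"], study.models)
    write_fastq(paths["reads"], study.reads)
    write_tsv(paths["counts"], study.counts.reset_index())
    write_tsv(paths["groups"], pd.DataFrame(
        {"sample_id": list(study.truth.groups),
         "group": list(study.truth.groups.values())}))
    write_fasta(paths["mirnas"], study.mirnas)
    write_fasta(paths["circ_seqs"], study.circ_seqs)
    write_fasta(paths["mrna_seqs"], study.mrna_seqs)
    write_tsv(paths["truth_circles"], pd.DataFrame(
        [{"circ_id": c.circ_id, "chrom": c.interval.chrom,
          "start": c.interval.start, "end": c.interval.end,
          "strand": c.interval.strand, "category": c.category,
          "splice_signal": c.splice_signal} for c in study.truth.circles]))
    write_tsv(paths["truth_de"], study.truth.de_labels)
    write_tsv(paths["truth_mres"], study.truth.mres)
    write_tsv(paths["gene_terms"], study.gene_terms)
    write_tsv(paths["size_factors"],
              study.truth.size_factors.rename_axis("sample_id").reset_index())
    return paths
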