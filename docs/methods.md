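# Methods

## Scope and model

`circlact` analyses bulk RNA-seq evidence for circular RNAs in three
layers: (i) sequence-level detection of back-splice junctions, (ii)
count-level inference of differential expression between two groups of
samples, and (iii) interaction-level inference of a
circRNA–miRNA–mRNA (ceRNA) network from shared miRNA binding sites.
Because raw sequencing data for this kind of study is rarely deposited,
the package carries a synthetic-study generator whose ground truth makes
every stage verifiable; the generator is part of the tested surface, not
a fixture.

## Read preprocessing

Four pure predicates run in a fixed order; a read is charged to the
first filter that removes it, and the report satisfies
`input = surviving + Σ removed` by construction.

| filter | rule | default |
| --- | --- | --- |
| low quality | discard iff fraction of bases with Phred ≥ Q is < f | Q = 20, f = 0.50 (strict "less than") |
| ambiguity | discard iff N fraction > t | t = 0.05 |
| adapter + length | trim longest 3′ suffix matching an adapter prefix (≥ 8 exact bases, iterated to a fixpoint), discard iff length < L | L = 20 |
| rRNA | discard iff any read k-mer occurs in the rRNA k-mer set (both strands) | k = 25 |

Two criteria that sometimes accompany such stacks — instrument
signal-strength extremes and per-base "error rate" proportions — describe
information FASTQ does not carry; the Q20 rule covers the recoverable
part and the rest is deliberately out of scope. The N threshold is a
package choice (none is standard); adapter matching is exact-prefix
rather than alignment-based, and rRNA removal is k-mer membership rather
than alignment — deterministic and adequate at desk scale.

## Back-splice detection

For each read the terminal `anchor_length` (default 20) bases are placed
by exact match against a forward-strand k-mer index. A linear read maps
colinearly; a junction-crossing read maps its 5′ anchor downstream of
its 3′ anchor. When both anchors hit uniquely on one chromosome in
reversed order within `max_span` (default 100 kb), the breakpoint is
slid across all offsets consistent with read/genome contiguity and fixed
at the first (leftmost) position whose flanks spell the canonical
signal: `AG | circle | GT` on the forward strand for a plus-strand
circle, the reverse-complement pair `AC | circle | CT` for a
minus-strand circle (found by rerunning on the reverse-complemented
read). Calls are aggregated by (chrom, start, end, strand) and reported
when supported by `min_junction_reads` (default 2) with an allowed
signal (default GT-AG only).

Anchors are exact because the generator emits error-free reads: the
detector is a deterministic stand-in for the published anchor-based
tools, not a mismatch-tolerant aligner. Reads with multi-mapping anchors
are skipped and counted. Reported coordinates are always on the forward
reference, 0-based half-open.

## Classification

Classification is span-based: a junction call fixes only the genomic
extent of the circle, not its internal splicing, so "exon-derived" is
judged on the span. Against genes on the call's own strand: span within
the exon union of one gene → EciRNA; span entirely inside one intron →
IciRNA; any other sense overlap (mixed exon/intron content or a span
extending outside the gene) → EIciRNA. With no sense overlap, an
opposite-strand gene overlap gives antisense; otherwise intergenic.
When several sense genes overlap, the largest-overlap gene wins (ties:
smaller gene start). GC content is computed on the genomic span sequence
((G+C)/non-N); summaries use fixed bins (length ≤200, 201–400, …,
>2000; GC decades 30–80%).

## Differential expression

Counts are junction-read counts per circRNA and sample. Size factors are
median-of-ratios: factor_j = median over rows of count_ij / geometric
row mean, computed over all-positive rows (falling back to rows positive
in ≥ half the samples). The expression level reported per circRNA is the
base mean — the mean of size-factor-normalized counts.

Testing uses the classical two-group NB conditional exact test. Counts
are summed within groups (kA, kB with summed size factors sA, sB), the
total K = kA + kB is conditioned on, and every split (a, K − a) is
scored by the product of NB probability masses with means q·sA and q·sB
where q = K/(sA + sB). The two-sided p-value is the total probability of
splits no more likely than the observed one, normalized over all splits.
At dispersion 0 the NB degenerates to Poisson, and with equal size
factors the conditional law is exactly Binomial(K, ½). A subtlety worth
stating: the sum of n replicate NB counts at per-sample dispersion α is
itself approximately NB with dispersion α·Σs_j²/(Σs_j)² (≈ α/n for
equal factors); `run_de` applies this conversion per group. Without it
the summed counts are modelled ~n-fold over-dispersed and the test loses
almost all power.

Dispersion is estimated per row by method of moments on normalized
counts (replicate variance around group means; Poisson floor at zero),
then shrunk toward a mean–dispersion trend a0 + a1/μ fitted across rows
by least squares. The default shrinkage weight is 0.75 toward the trend:
with 3 samples per group the per-row estimate has only 4 residual
degrees of freedom, and because the exact test's rejection rate is
convex in the assumed dispersion, unshrunk estimation noise makes the
null test liberal (~0.06 at nominal 0.05 in simulation); weight 0.75
restores the nominal level with no measurable loss of power at planted
log2FC = 2. The weight is configurable.

Significance defaults to |log2FC| ≥ 1 and BH-adjusted p < 0.05 (both
configurable; raw and adjusted p are both reported). Fold changes are
group B (early lactation) over group A (non-lactation) on normalized
group means; all-zero rows are reported with p = 1 and an undefined fold
change, never dropped.

## ceRNA scoring and network

An MRE is an exact reverse-complement match of the miRNA seed (positions
2–8; 7-mer by default, configurable span) in the RNA sequence, counted
greedily left to right without overlap. The full alignment/energy model
of miRanda-style predictors is intentionally replaced by seed matching:
the downstream score and test consume only MRE counts, which seed
matching supplies deterministically.

For each circRNA×mRNA pair with at least one shared miRNA, the score is
the fraction of the circRNA's MREs belonging to shared miRNAs. The
typeset form of this ratio is ambiguous about whether mRNA-side sites
enter the numerator; this package counts circRNA-side sites only
(starBase-style) and isolates the choice in one function
(`cerna.cerna_score`) so the other reading can be swapped in. The
sharing p-value is the hypergeometric upper tail (formula in the
README), evaluated in log space with `lgamma`; `M_T` is the number of
miRNAs supplied to the run, not a genome-wide constant. The filter keeps
pairs with m_c ≥ 3 and p ≤ 0.05 (raw p, matching the filtering
convention the score comes from; BH adjustment is available but off by
default), ranked by score desc, m_c desc, pair id. The exported graph
contains exactly the retained pairs, their shared miRNAs and the
targeting edges — no orphan nodes.

The enrichment module reuses the same tail kernel with
(M_T, m_n, m_p, m_c) = (N, K, n, k); term maps are local inputs because
remote annotation databases make counts irreproducible.

## Synthetic study generator

The generator emulates the study design the pipeline targets: two
groups (early lactation vs non-lactation) of 3 samples each, ~50
circRNAs across all five categories, GT-AG junctions, NB junction
counts. Defaults, chosen once as a realistic desk-scale study:

- genome: 3 chromosomes × 120 kb, 12 genes (3–5 exons of 150–400 bp,
  introns 600–2,500 bp, strands alternating, wide intergenic gaps);
- circles: 10 per category, lengths 48–5,000 bp (the upper end of the
  observed biological range, ~100 kb, is available by config but kept
  small by default for test speed); spans padded by 30 bp never overlap,
  so every junction is unambiguous; flank dinucleotides are written into
  the genome on the circle's strand;
- reads: length 50 with 20-base minimum overhang on each side of the
  breakpoint. Read length is deliberately short: a junction read of
  length L shows reversed-order anchors only when the circle is longer
  than L − 20, and L = 50 keeps even 48 bp circles detectable.
  Background reads (default 300) are colinear genome fragments on either
  strand; there is no sequencing-error model because the detector is an
  exact-match method — errors would only exercise an aligner the package
  does not claim to be;
- counts: baseline means log-uniform on [20, 500], dispersion 0.1,
  size factors 2^U(−0.5, 0.5), 20% of circles differentially expressed
  at log2FC ±2 (half up, half down). No published values exist for
  library size or dispersion in this setting; these are conventions,
  stated here once;
- miRNA sites: 20 miRNAs (22 nt) with pairwise-distinct seeds; selected
  RNAs receive 1–4 non-overlapping exact seed-complement sites with ≥
  7 bp spacing. Accidental seed complements elsewhere are removed by
  resampling non-site bases (every accidental occurrence necessarily
  touches a gap base), so the truth tables are exact rather than
  approximate.

What the generator does **not** emulate: sequencing errors and quality
variation, isoform structure inside circles, rolling-circle reads that
traverse the junction more than once, GC or positional bias, and
biological correlation between counts and sequence content. Passing
tests therefore demonstrate correctness of the algorithms under their
stated assumptions, not robustness to real-data noise.

## Numerical and degenerate-input conventions

- Exact-test ties are compared with a 1 + 1e−10 relative tolerance so
  float rounding cannot split equal-probability outcomes.
- Poisson is used below dispersion 1e−8 (the NB size parameter would
  overflow).
- Breakpoint ambiguity (several contiguity-consistent offsets) resolves
  to the leftmost offset with a valid signal.
- K = 0 (both groups zero) gives p = 1; a circRNA with no MREs is not a
  ceRNA candidate rather than a division by zero; an all-N sequence has
  undefined GC, reported as missing.
- All randomness flows from one seeded NumPy generator per study; file
  writers are plain-text and order-stable, giving byte-identical reruns.

## Known limitations

- The detector requires exact, unique anchor matches; repetitive genomes
  or error-containing reads need a real aligner.
- Span-based classification cannot distinguish a fully exonic mature
  circle from an exon–intron circle when the span crosses an intron.
- The exact test conditions on plug-in estimates (total-count mean and
  moment-based dispersion); calibration is demonstrated by simulation at
  the default study size, not guaranteed for designs far from it.
- Seed matching ignores binding energetics, 3′-compensatory pairing and
  conservation; MRE counts are an upper bound on functional sites.
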