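# circlact

Circular RNAs (circRNAs) arise when a downstream splice donor joins an
upstream acceptor, producing a covalently closed transcript whose
back-splice junction is the only sequence feature distinguishing it from
its linear host. `circlact` is a desk-scale, fully deterministic
reimplementation of a bulk RNA-seq circRNA study pipeline — the kind used
to profile circRNAs in mammary tissue across lactation stages — aimed at
method developers and students who want every stage runnable, inspectable
and testable without external data or databases:

1. **Read preprocessing** (`circlact.qc`) — quality (Q20 / 50% rule),
   N-ambiguity, adapter + length, and rRNA k-mer filters, with exact
   per-filter accounting.
2. **Back-splice detection** (`circlact.detect`) — terminal anchors of
   each read are placed by exact match; a junction is called when the
   anchors map uniquely in *reversed* genomic order and the breakpoint
   extends to a canonical GT‑AG donor/acceptor signal.
3. **Classification & characterization** (`circlact.annotate`) — each
   call becomes one of five source categories (EciRNA, IciRNA, EIciRNA,
   antisense, intergenic) against gene models, plus length/GC/exon/
   chromosome summaries.
4. **Differential expression** (`circlact.diffexpr`) — median-of-ratios
   size factors, base means, and a two-group negative binomial
   conditional exact test with Benjamini–Hochberg adjustment.
5. **ceRNA network** (`circlact.cerna`) — miRNA response elements (MREs)
   by exact seed (positions 2–8) complement matching; for each
   circRNA–mRNA pair sharing miRNAs,

   ```
   ceRNA_score = #MREs of shared miRNAs on the circRNA / #MREs on the circRNA (all miRNAs)

   p = Σ_{i=m_c}^{min(m_p, m_n)}  C(m_n, i) · C(M_T − m_n, m_p − i) / C(M_T, m_p)
   ```

   where `M_T` is the number of miRNAs in the analysis, `m_p`/`m_n` the
   numbers targeting the mRNA/circRNA, and `m_c` the shared count. Pairs
   with fewer than 3 shared miRNAs or p > 0.05 are filtered; the network
   is exported as GraphML and Cytoscape-loadable TSVs.
6. **Enrichment** (`circlact.enrichment`) — a local hypergeometric
   over-representation test of parent genes against user-supplied term
   maps (GMT or two-column TSV).
7. **Synthetic study generator** (`circlact.synth`) — first-class,
   tested code that builds a genome with gene models, plants circRNAs of
   all five categories with GT‑AG flanks, simulates junction-spanning
   reads, NB junction counts with planted fold changes, and miRNA seed
   sites at exact multiplicities — so every downstream stage can be
   checked against ground truth.

## Worked example

```python
from circlact import synth, detect, annotate, diffexpr

study = synth.generate_study(synth.SyntheticConfig(seed=5))
index = detect.build_anchor_index(study.genome, 20)
calls, _ = detect.call_circrnas(study.reads, index, study.genome)
anns = annotate.annotate_calls(calls, study.models, study.genome)
summary = annotate.summarize(anns, calls)
print(len(calls), summary.mean_length, summary.category_counts)

res = diffexpr.run_de(study.counts, study.truth.groups)
print(res.head(3))
```

prints

```
50 1127.66 {'EciRNA': 10, 'IciRNA': 10, 'EIciRNA': 10, 'antisense': 10, 'intergenic': 10}
     circ_id   base_mean  log2_fold_change   p_value  adjusted_p  significant direction
0  circ_0033  138.888740         -2.000181  0.000004    0.000096         True      down
1  circ_0047  494.532167          2.024090  0.000003    0.000096         True        up
2  circ_0004  111.715253         -2.220936  0.000007    0.000114         True      down
```

All 50 planted junctions are recovered at exact coordinates with the
GT‑AG signal and classified into their planted categories; the top
differential circRNAs carry fold-change estimates close to the planted
log2FC of ±2.

The same run is available from the shell:

```bash
circlact run --seed 5 --outdir run/
```

which executes synth → qc → detect → annotate → de → cerna → enrich and
writes a `manifest.json` recording the seed, a configuration hash and a
checksum for every output file (two runs with the same seed are
byte-identical). Individual stages are exposed as `circlact synth|qc|
detect|annotate|de|cerna|enrich`.

## Layout

```
src/circlact/
  io_formats.py   FASTA/GFF3/FASTQ/BED/TSV/GraphML, 0-based half-open API
  synth.py        synthetic study generator + ground truth
  qc.py           read filter stack
  detect.py       anchor-based back-splice detection
  annotate.py     five-way classification + characterization
  diffexpr.py     size factors, NB exact test, dispersion, BH
  cerna.py        MRE prediction, ceRNA score, shared-miRNA test, network
  enrichment.py   hypergeometric over-representation
  pipeline.py     stage orchestration + manifest
  cli.py          click command line
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
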