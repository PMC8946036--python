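"""End-to-end orchestration: synth -> qc -> detect -> annotate -> de ->
cerna -> enrich, with a run manifest for reproducibility audits.

Every stage writes plain-text outputs under its own subdirectory; the
manifest records the seed, a hash of the effective configuration, row
counts per stage and a checksum per output file, so two runs with the
same configuration can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as annotate_mod
from . import cerna as cerna_mod
from . import detect as detect_mod
from . import diffexpr, enrichment, qc, synth
from .detect import CircCall
from .io_formats import write_bed, write_graphml, write_tsv

STAGES = ("synth", "qc", "detect", "annotate", "de", "cerna", "enrich")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | Path = "circlact_run"
    stages: tuple[str, ...] = STAGES
    synth: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    detector: detect_mod.DetectorConfig = field(default_factory=detect_mod.DetectorConfig)
    de: diffexpr.DEThresholds = field(default_factory=diffexpr.DEThresholds)
    network: cerna_mod.NetworkThresholds = field(default_factory=cerna_mod.NetworkThresholds)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.synth.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in ("seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        for key, ctor in [("synth", synth.SyntheticConfig), ("qc", qc.QCConfig),
                          ("detector", detect_mod.DetectorConfig),
                          ("de", diffexpr.DEThresholds),
                          ("network", cerna_mod.NetworkThresholds)]:
            if key in raw:
                section = dict(raw[key])
                for f in dataclasses.fields(ctor):
                    if f.name in section and isinstance(section[f.name], list):
                        section[f.name] = tuple(section[f.name])
                kwargs[key] = ctor(**section)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, Path):
                return str(obj)
            return obj

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the manifest dict.

    A stage whose inputs were not produced (toggled-off upstream stage)
    raises :class:`PipelineError` naming the missing input.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "files": {},
    }

    def record(stage: str, counts: dict, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = counts
        for name, path in files.items():
            manifest["files"][f"{stage}/{name}"] = _sha256(Path(path))

    def need(path: Path, stage: str, produced_by: str) -> Path:
        if not path.exists():
            raise PipelineError(
                f"stage '{stage}' needs {path.name}, produced by stage "
                f"'{produced_by}' which did not run"
            )
        return path

    sdir = outdir / "synth"
    study = None
    if "synth" in config.stages:
        study = synth.generate_study(config.synth, sdir)
        record("synth", {
            "circles": len(study.truth.circles),
            "reads": len(study.reads),
            "genes": len(study.models),
            "mirnas": len(study.mirnas),
        }, {p.name: p for p in sorted(sdir.iterdir())})

    from .io_formats import read_fasta, read_gff3, stream_fastq

    clean_fastq = outdir / "qc" / "clean.fastq"
    if "qc" in config.stages:
        (outdir / "qc").mkdir(exist_ok=True)
        reads_path = need(sdir / "reads.fastq", "qc", "synth")
        report = qc.run_qc_file(reads_path, clean_fastq, config.qc)
        report_path = outdir / "qc" / "qc_report.json"
        report_path.write_text(json.dumps({
            "input_reads": report.input_reads,
            "surviving_reads": report.surviving_reads,
            "removed_by_filter": report.removed_by_filter,
        }, indent=2) + "\n")
        record("qc", {"input": report.input_reads,
                      "surviving": report.surviving_reads},
               {"clean.fastq": clean_fastq, "qc_report.json": report_path})

    calls: list[CircCall] = []
    genome = models = None
    ddir = outdir / "detect"
    if "detect" in config.stages:
        ddir.mkdir(exist_ok=True)
        genome = read_fasta(need(sdir / "genome.fa", "detect", "synth"))
        index = detect_mod.build_anchor_index(genome, config.detector.anchor_length)
        reads = stream_fastq(need(clean_fastq, "detect", "qc"))
        calls, det_report = detect_mod.call_circrnas(reads, index, genome, config.detector)
        bed_path, tsv_path = ddir / "circrnas.bed", ddir / "circrnas.tsv"
        write_bed(bed_path, [(c.interval, c.circ_id, c.junction_reads) for c in calls])
        write_tsv(tsv_path, pd.DataFrame([
            {"circ_id": c.circ_id, "chrom": c.interval.chrom,
             "start": c.interval.start, "end": c.interval.end,
             "strand": c.strand, "junction_reads": c.junction_reads,
             "splice_signal": c.splice_signal,
             **{f"reads_{s}": n for s, n in c.sample_counts.items()}}
            for c in calls]))
        record("detect", {"calls": len(calls),
                          "reads_seen": det_report.reads_seen,
                          "ambiguous": det_report.ambiguous_anchor},
               {"circrnas.bed": bed_path, "circrnas.tsv": tsv_path})

    if "annotate" in config.stages:
        adir = outdir / "annotate"
        adir.mkdir(exist_ok=True)
        if genome is None:
            genome = read_fasta(need(sdir / "genome.fa", "annotate", "synth"))
        models = read_gff3(need(sdir / "genes.gff3", "annotate", "synth"))
        if not (ddir / "circrnas.tsv").exists():
            raise PipelineError("stage 'annotate' needs detect output")
        annotations = annotate_mod.annotate_calls(calls, models, genome)
        summary = annotate_mod.summarize(annotations, calls)
        ann_path = adir / "annotations.tsv"
        write_tsv(ann_path, pd.DataFrame([dataclasses.asdict(a) for a in annotations]))
        summary_path = adir / "summary.json"
        summary_path.write_text(
            json.dumps(dataclasses.asdict(summary), indent=2, default=str) + "\n")
        record("annotate", {"annotated": len(annotations)},
               {"annotations.tsv": ann_path, "summary.json": summary_path})

    de_results = None
    if "de" in config.stages:
        dedir = outdir / "de"
        dedir.mkdir(exist_ok=True)
        counts = pd.read_csv(need(sdir / "counts.tsv", "de", "synth"),
                             sep="\t", index_col="circ_id")
        groups_df = pd.read_csv(need(sdir / "groups.tsv", "de", "synth"), sep="\t")
        groups = dict(zip(groups_df["sample_id"], groups_df["group"]))
        de_results = diffexpr.run_de(counts, groups, config.de)
        de_path = dedir / "de_results.tsv"
        write_tsv(de_path, de_results)
        record("de", {"tested": len(de_results),
                      "significant": int(de_results["significant"].sum())},
               {"de_results.tsv": de_path})

    if "cerna" in config.stages:
        cdir = outdir / "cerna"
        cdir.mkdir(exist_ok=True)
        mirnas = read_fasta(need(sdir / "mirnas.fa", "cerna", "synth"))
        circ_seqs = read_fasta(need(sdir / "circ_seqs.fa", "cerna", "synth"))
        mrna_seqs = read_fasta(need(sdir / "mrna_seqs.fa", "cerna", "synth"))
        mre_table = pd.concat([
            cerna_mod.predict_mres_table(circ_seqs, "circRNA", mirnas),
            cerna_mod.predict_mres_table(mrna_seqs, "mRNA", mirnas),
        ], ignore_index=True)
        graph, ranked = cerna_mod.build_network(mre_table, config.network,
                                                M_T=len(mirnas))
        mre_path, pair_path = cdir / "mre_table.tsv", cdir / "cerna_pairs.tsv"
        gml_path = cdir / "network.graphml"
        write_tsv(mre_path, mre_table)
        write_tsv(pair_path, ranked)
        write_graphml(gml_path, graph)
        nodes = pd.DataFrame(
            [{"node": n, "node_type": d["node_type"]}
             for n, d in sorted(graph.nodes(data=True))])
        edges = pd.DataFrame(
            [{"source": u, "target": v, **{k: str(val) for k, val in d.items()}}
             for u, v, d in sorted(graph.edges(data=True))])
        nodes_path, edges_path = cdir / "nodes.tsv", cdir / "edges.tsv"
        write_tsv(nodes_path, nodes)
        write_tsv(edges_path, edges)
        record("cerna", {"mre_rows": len(mre_table), "pairs_kept": len(ranked)},
               {"mre_table.tsv": mre_path, "cerna_pairs.tsv": pair_path,
                "network.graphml": gml_path, "nodes.tsv": nodes_path,
                "edges.tsv": edges_path})

    if "enrich" in config.stages:
        edir = outdir / "enrich"
        edir.mkdir(exist_ok=True)
        term_path = need(sdir / "gene_terms.tsv", "enrich", "synth")
        terms = enrichment.read_term_map(term_path)
        if de_results is None:
            raise PipelineError("stage 'enrich' needs de output")
        if models is None:
            models = read_gff3(need(sdir / "genes.gff3", "enrich", "synth"))
        truth_circ = pd.read_csv(need(sdir / "truth_circles.tsv", "enrich", "synth"),
                                 sep="\t")
        # parent genes of the significant circles, via span classification
        from .io_formats import GenomicInterval

        sig_ids = set(de_results.loc[de_results["significant"], "circ_id"])
        pseudo_calls = [
            CircCall(row.circ_id,
                     GenomicInterval(row.chrom, row.start, row.end, row.strand),
                     junction_reads=1, splice_signal="GT-AG", breakpoint_reads=[])
            for row in truth_circ.itertuples(index=False)
            if row.circ_id in sig_ids
        ]
        anns = annotate_mod.annotate_calls(pseudo_calls, models)
        study_genes = sorted({a.parent_gene for a in anns if a.parent_gene})
        universe = sorted({gm.gene_id for gm in models})
        result = enrichment.enrich(study_genes, terms, universe)
        enr_path = edir / "enrichment.tsv"
        write_tsv(enr_path, result)
        record("enrich", {"terms": len(result), "study_genes": len(study_genes)},
               {"enrichment.tsv": enr_path})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
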