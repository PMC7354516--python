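"""End-to-end orchestration: qc -> subtract -> assemble -> decontam ->
annotate -> quant -> temporal (+ host DE, + growth when a PFU table is given),
driven by one config, with file-based staging, a manifest, and a run report.

Every stage reads the previous stage's files under the output directory, so
any stage can be re-run from cached upstream outputs; record counts are
carried through the report and must be conserved stage to stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import assemble as asm
from . import decontam as dec
from . import diffexpr as dex
from . import qc as qcmod
from . import subtract as sub
from . import temporal as tmp
from .growth import GrowthCurve, normalize_curve, estimate_params
from .kmers import build_index
from .quant import SampleSpec, build_gene_index, count_matrix, CountMatrix
from .seqs import (read_fasta, write_fasta, read_fastq_pairs, write_fastq_pairs,
                   read_gff3, write_gff3)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str
    host_fasta: str
    sample_sheet: str
    host_gff: str | None = None
    plasmid_fasta: str | None = None
    pfu_table: str | None = None
    seed: int = 0
    # qc
    qc_window: int = 4
    qc_min_q: int = 20
    qc_min_len: int = 50
    # subtraction / decontamination (shared host index)
    subtract_k: int = 25
    subtract_threshold: float = 0.5
    identity_max: float = 0.9
    scaffold_min_len: int = 1000
    # assembly
    assembler_k: int = 31
    assembler_min_count: int = 2
    tip_max_len: int | None = None
    pop_bubbles: bool = True
    bubble_ratio: float = 0.25
    min_contig_len: int | None = None      # default 2k
    insert_mean: float = 220.0
    insert_sd: float = 30.0
    scaffold_min_links: int = 3
    # annotation
    min_codons: int = 30
    rbs_high: int = 4
    # quantification
    quant_k: int = 25
    quant_min_hits: int = 10
    # temporal
    min_cpm: float = 1.0
    # differential expression
    de_alpha: float = 0.001
    de_use_fdr: bool = False


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, info: dict, t0: float, files: list[Path]) -> None:
        self.stages[stage] = info
        self.timings[stage] = round(time.perf_counter() - t0, 2)
        self.outputs[stage] = [str(f) for f in files]


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "fastq1", "fastq2", "experiment", "timepoint_min", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [SampleSpec(r.sample, r.fastq1, r.fastq2, r.experiment,
                       float(r.timepoint_min), int(r.replicate))
            for r in df.itertuples()]


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    samples = read_sample_sheet(config.sample_sheet)
    host_records = read_fasta(config.host_fasta)
    if config.plasmid_fasta:
        host_records.update(read_fasta(config.plasmid_fasta))
    try:
        _run_stages(config, out, report, samples, host_records)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    manifest = {"config": asdict(config), "stages": report.stages,
                "timings_s": report.timings,
                "files": {name: _md5(p) for stage in report.outputs.values()
                          for name, p in ((Path(f).name, Path(f)) for f in stage)
                          if p.exists()}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(out / "run_report.json", "w") as fh:
        json.dump({"stages": report.stages, "timings_s": report.timings},
                  fh, indent=2, sort_keys=True, default=str)
    return report


def _run_stages(config: PipelineConfig, out: Path, report: RunReport,
                samples: list[SampleSpec], host_records: dict[str, str]) -> None:
    # --- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    qc_rows, qc_files = [], []
    qc_samples: list[SampleSpec] = []
    for s in samples:
        rep = qcmod.QcReport()
        kept = qcmod.filter_pairs(read_fastq_pairs(s.fastq1, s.fastq2),
                                  config.qc_window, config.qc_min_q,
                                  config.qc_min_len, rep)
        f1 = qc_dir / f"{s.name}_1.fastq"
        f2 = qc_dir / f"{s.name}_2.fastq"
        write_fastq_pairs(f1, f2, kept)
        qc_rows.append({"sample": s.name, **rep.as_dict()})
        qc_files += [f1, f2]
        qc_samples.append(SampleSpec(s.name, str(f1), str(f2), s.experiment,
                                     s.timepoint_min, s.replicate))
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
    report.record("qc", {"pairs_in": int(qc_df.pairs_in.sum()),
                         "pairs_kept": int(qc_df.pairs_kept.sum())},
                  t0, qc_files + [qc_dir / "qc_report.tsv"])

    # --- subtraction -------------------------------------------------------
    t0 = time.perf_counter()
    sub_dir = out / "subtract"
    sub_dir.mkdir(exist_ok=True)
    host_index = build_index(list(host_records.values()), config.subtract_k,
                             source_ids=list(host_records))
    sub_rows, sub_files = [], []
    nonhost_pool = []
    for s in qc_samples:
        host_pool, nonhost, rep = sub.subtract_pairs(
            read_fastq_pairs(s.fastq1, s.fastq2), host_index,
            config.subtract_threshold)
        h1, h2 = sub_dir / f"{s.name}_host_1.fastq", sub_dir / f"{s.name}_host_2.fastq"
        n1, n2 = sub_dir / f"{s.name}_nonhost_1.fastq", sub_dir / f"{s.name}_nonhost_2.fastq"
        write_fastq_pairs(h1, h2, host_pool)
        write_fastq_pairs(n1, n2, nonhost)
        nonhost_pool.extend(nonhost)
        sub_rows.append({"sample": s.name, **rep.as_dict()})
        sub_files += [h1, h2, n1, n2]
    sub_df = pd.DataFrame(sub_rows)
    sub_df.to_csv(sub_dir / "subtract_report.tsv", sep="\t", index=False)
    report.record("subtract", {"pairs_in": int(sub_df.pairs_in.sum()),
                               "pairs_host": int(sub_df.pairs_host.sum()),
                               "pairs_nonhost": int(sub_df.pairs_nonhost.sum())},
                  t0, sub_files + [sub_dir / "subtract_report.tsv"])

    # --- assembly ----------------------------------------------------------
    t0 = time.perf_counter()
    asm_dir = out / "assemble"
    asm_dir.mkdir(exist_ok=True)
    k = config.assembler_k
    reads = [p.seq1 for p in nonhost_pool] + [p.seq2 for p in nonhost_pool]
    graph = asm.build_graph(reads, k, config.assembler_min_count)
    if config.pop_bubbles:
        asm.clean_graph(graph, config.tip_max_len or 2 * k, config.bubble_ratio)
    else:
        asm.prune(graph, config.tip_max_len or 2 * k)
    contigs = asm.extract_unitigs(graph, config.min_contig_len or 2 * k)
    # linking saturates quickly; a deterministic stride-subsample of the pool
    # keeps scaffolding O(30k pairs) at any depth
    stride = max(1, len(nonhost_pool) // 30_000)
    scaffolds = asm.scaffold_contigs(contigs, nonhost_pool[::stride],
                                     config.insert_mean, config.insert_sd,
                                     config.scaffold_min_links, k=k)
    write_fasta(asm_dir / "scaffolds.fasta",
                [(s.id, s.sequence) for s in scaffolds])
    stats = asm.assembly_stats(scaffolds)
    pd.DataFrame(stats.table(), columns=["ID", "Size_bp", "GC_pct"]).to_csv(
        asm_dir / "assembly_stats.tsv", sep="\t", index=False)
    report.record("assemble", {"nonhost_pairs": len(nonhost_pool),
                               "graph_kmers": len(graph),
                               "contigs": len(contigs),
                               "scaffolds": len(scaffolds),
                               "total_bp": stats.total_bp, "n50": stats.n50},
                  t0, [asm_dir / "scaffolds.fasta", asm_dir / "assembly_stats.tsv"])

    # --- decontamination ---------------------------------------------------
    t0 = time.perf_counter()
    dec_dir = out / "decontam"
    dec_dir.mkdir(exist_ok=True)
    kept, excluded, fates = dec.filter_scaffolds(scaffolds, host_index,
                                                 config.identity_max,
                                                 config.scaffold_min_len)
    # renumber kept scaffolds by length so downstream ids stay dense
    kept = sorted(kept, key=lambda s: (-s.length, s.sequence))
    for i, s in enumerate(kept, 1):
        s.id = f"scaffold_{i}"
    write_fasta(dec_dir / "kept.fasta", [(s.id, s.sequence) for s in kept])
    write_fasta(dec_dir / "excluded.fasta", [(s.id, s.sequence) for s in excluded])
    pd.DataFrame([asdict(f) for f in fates]).to_csv(
        dec_dir / "decontam_report.tsv", sep="\t", index=False)
    kept_stats = asm.assembly_stats(kept)
    pd.DataFrame(kept_stats.table(), columns=["ID", "Size_bp", "GC_pct"]).to_csv(
        dec_dir / "kept_stats.tsv", sep="\t", index=False)
    report.record("decontam", {"scaffolds_in": len(scaffolds),
                               "kept": len(kept), "excluded": len(excluded),
                               "kept_bp": kept_stats.total_bp},
                  t0, [dec_dir / "kept.fasta", dec_dir / "excluded.fasta",
                       dec_dir / "decontam_report.tsv", dec_dir / "kept_stats.tsv"])

    # --- annotation ---------------------------------------------------------
    t0 = time.perf_counter()
    ann_dir = out / "annotate"
    ann_dir.mkdir(exist_ok=True)
    kept_seqs = {s.id: s.sequence for s in kept}
    genes = ann.call_genes(kept_seqs, config.min_codons, rbs_high=config.rbs_high)
    write_gff3(ann_dir / "genes.gff3", ann.genes_to_gff(genes))
    write_fasta(ann_dir / "genes.fasta",
                [(g.id, g.extract(kept_seqs[g.scaffold])) for g in genes])
    write_fasta(ann_dir / "proteins.fasta",
                [(g.id, g.protein(kept_seqs[g.scaffold])) for g in genes])
    report.record("annotate", {"genes": len(genes),
                               "high_confidence": sum(g.confidence == "high"
                                                      for g in genes)},
                  t0, [ann_dir / "genes.gff3", ann_dir / "genes.fasta",
                       ann_dir / "proteins.fasta"])

    # --- quantification ------------------------------------------------------
    t0 = time.perf_counter()
    q_dir = out / "quant"
    q_dir.mkdir(exist_ok=True)
    gene_ids = [g.id for g in genes]
    gene_seqs = [g.extract(kept_seqs[g.scaffold]) for g in genes]
    host_gene_ids: list[str] = []
    if config.host_gff:
        host_feats = read_gff3(config.host_gff)
        for f in host_feats:
            gid = f.attributes.get("ID", f"{f.seqid}:{f.start}-{f.end}")
            seq = host_records[f.seqid][f.start - 1:f.end]
            gene_ids.append(gid)
            gene_seqs.append(seq)
            host_gene_ids.append(gid)
    gindex = build_gene_index(gene_ids, gene_seqs, config.quant_k)
    cm = count_matrix(qc_samples, gindex, config.quant_min_hits)
    cm.counts.to_csv(q_dir / "counts.tsv", sep="\t")
    cm.meta.assign(ambiguous=cm.ambiguous, unassigned=cm.unassigned).to_csv(
        q_dir / "quant_summary.tsv", sep="\t")
    report.record("quant", {"genes": len(gene_ids),
                            "assigned": int(cm.counts.to_numpy().sum()),
                            "ambiguous": int(cm.ambiguous.sum()),
                            "unassigned": int(cm.unassigned.sum())},
                  t0, [q_dir / "counts.tsv", q_dir / "quant_summary.tsv"])

    # --- temporal classes (phage genes) --------------------------------------
    t0 = time.perf_counter()
    tdir = out / "temporal"
    tdir.mkdir(exist_ok=True)
    phage_ids = [g.id for g in genes]
    phage_cm = CountMatrix(cm.counts.loc[phage_ids], cm.meta,
                           cm.ambiguous, cm.unassigned)
    cpm = tmp.cpm_normalize(phage_cm)
    classes = tmp.classify(cpm, min_cpm=config.min_cpm)
    classes.to_csv(tdir / "classes.tsv", sep="\t")
    heat, _ = tmp.rowmax_normalize(cpm)
    heat.to_csv(tdir / "heatmap_matrix.tsv", sep="\t")
    summary = tmp.class_summary(classes["class"])
    summary.to_csv(tdir / "class_summary.tsv", sep="\t")
    report.record("temporal",
                  {"genes": len(classes),
                   **{c: int(n) for c, n in summary["n_genes"].items()}},
                  t0, [tdir / "classes.tsv", tdir / "heatmap_matrix.tsv",
                       tdir / "class_summary.tsv"])

    # --- host differential expression ----------------------------------------
    if host_gene_ids:
        t0 = time.perf_counter()
        ddir = out / "de"
        ddir.mkdir(exist_ok=True)
        host_cm = CountMatrix(cm.counts.loc[host_gene_ids], cm.meta,
                              cm.ambiguous, cm.unassigned)
        de_files = []
        de_info = {}
        for exp in sorted(cm.meta["experiment"].unique()):
            m = cm.meta[cm.meta["experiment"] == exp]
            if 0.0 not in set(m["timepoint_min"]) or len(m) < 3:
                continue
            res = dex.call_de(host_cm, alpha=config.de_alpha,
                              use_fdr=config.de_use_fdr, experiment=exp)
            f = ddir / f"de_{exp}.tsv"
            res.table.to_csv(f, sep="\t", index=False)
            fs = ddir / f"de_{exp}_summary.tsv"
            res.summary.to_csv(fs, sep="\t")
            de_files += [f, fs]
            de_info[exp] = {"n_significant": int(res.table.significant.sum()),
                            "dispersion": res.dispersion}
        report.record("de", de_info, t0, de_files)

    # --- growth curve ----------------------------------------------------------
    if config.pfu_table:
        t0 = time.perf_counter()
        gdir = out / "growth"
        gdir.mkdir(exist_ok=True)
        df = pd.read_csv(config.pfu_table, sep="\t")
        curve = GrowthCurve(df["time_min"].tolist(),
                            df["pfu_untreated"].tolist(),
                            df["pfu_chloroform"].tolist()
                            if "pfu_chloroform" in df else None)
        params = estimate_params(normalize_curve(curve))
        with open(gdir / "growth_params.json", "w") as fh:
            json.dump(asdict(params), fh, indent=2)
        report.record("growth", asdict(params), t0, [gdir / "growth_params.json"])


def summarize(outdir: str | Path) -> dict:
    """Combine stage outputs into the end-of-run report: per-scaffold
    assembly rows with TOTAL/Average, temporal class counts with percentages,
    and DE counts per contrast."""
    out = Path(outdir)
    result: dict = {}
    stats_path = out / "decontam" / "kept_stats.tsv"
    if stats_path.exists():
        result["assembly"] = pd.read_csv(stats_path, sep="\t").to_dict("records")
    cls_path = out / "temporal" / "class_summary.tsv"
    if cls_path.exists():
        result["temporal_classes"] = pd.read_csv(cls_path, sep="\t").to_dict("records")
    de_dir = out / "de"
    if de_dir.exists():
        result["de"] = {}
        for f in sorted(de_dir.glob("de_*_summary.tsv")):
            result["de"][f.stem] = pd.read_csv(f, sep="\t").to_dict("records")
    growth_path = out / "growth" / "growth_params.json"
    if growth_path.exists():
        result["growth"] = json.loads(growth_path.read_text())
    with open(out / "summary.json", "w") as fh:
        json.dump(result, fh, indent=2, default=str)
    return result


def summarize_scaffold_rows(rows: list[tuple[str, int, float]]) -> list[tuple]:
    """Table-2-style report from (id, length, GC%) rows: per-scaffold lines
    plus the TOTAL/Average line (half-up 1-decimal GC)."""
    return asm.stats_from_rows(rows).table()
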