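"""Scoring pipeline outputs against simulator ground truth.

Assembled scaffolds have no coordinate system shared with the true genome, so
recovery is measured through exact k-mers and exact gene sequences: a genome
position counts as recovered when some kept-scaffold k-mer that occurs in the
true phage genome covers it, and a gene counts as exactly recovered when a
called gene's coding sequence equals the true gene's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .assemble import Scaffold
from .kmers import kmer_codes
from .simulate import SimTruth


def phage_base_recovery(truth: SimTruth, scaffolds: list[Scaffold],
                        k: int = 31) -> float:
    """Fraction of true phage genome positions covered by scaffold k-mers
    that occur in the true genome (N-gap windows contribute nothing)."""
    genome = truth.phage_genome
    pos_of: dict[int, list[int]] = {}
    for i, c in enumerate(kmer_codes(genome, k).tolist()):
        pos_of.setdefault(c, []).append(i)
    covered = np.zeros(len(genome), dtype=bool)
    for s in scaffolds:
        for part in s.sequence.split("N"):
            if len(part) < k:
                continue
            for c in kmer_codes(part, k).tolist():
                for p in pos_of.get(c, ()):
                    covered[p:p + k] = True
    return float(covered.mean())


def gene_recovery(truth: SimTruth, called: list[GeneModel],
                  scaffold_seqs: dict[str, str]) -> dict[str, float]:
    """Exact-coordinate gene recovery via exact coding-sequence identity.

    recall: fraction of true genes recovered exactly; precision: fraction of
    called genes that equal some true gene.
    """
    true_seqs = {truth.gene_seq(g) for g in truth.phage_genes}
    called_seqs = [g.extract(scaffold_seqs[g.scaffold]) for g in called]
    n_exact = sum(1 for s in called_seqs if s in true_seqs)
    recovered = true_seqs & set(called_seqs)
    return {
        "recall": len(recovered) / len(true_seqs) if true_seqs else 0.0,
        "precision": n_exact / len(called_seqs) if called_seqs else 0.0,
        "n_true": len(true_seqs), "n_called": len(called_seqs),
    }


def match_called_to_truth(truth: SimTruth, called: list[GeneModel],
                          scaffold_seqs: dict[str, str]) -> dict[str, str]:
    """called gene id -> truth gene id, by exact coding-sequence identity."""
    by_seq = {truth.gene_seq(g): g.id for g in truth.phage_genes}
    out = {}
    for g in called:
        tid = by_seq.get(g.extract(scaffold_seqs[g.scaffold]))
        if tid is not None:
            out[g.id] = tid
    return out


def class_recovery(truth: SimTruth, classes: pd.Series,
                   called: list[GeneModel],
                   scaffold_seqs: dict[str, str]) -> dict[str, float]:
    """Fraction of truth-matched, non-artifact called genes whose assigned
    temporal class equals the truth class."""
    mapping = match_called_to_truth(truth, called, scaffold_seqs)
    n = hit = 0
    for cid, tid in mapping.items():
        if cid not in classes.index:
            continue
        got = classes[cid]
        if got == "artifact":
            continue
        n += 1
        hit += got == truth.classes[tid]
    return {"accuracy": hit / n if n else 0.0, "n_scored": n,
            "n_matched": len(mapping)}


def subtraction_confusion(labels: pd.DataFrame, host_ids: set[str],
                          nonhost_ids: set[str]) -> dict[str, float]:
    """Recall of phage pairs into the nonhost pool and host leakage into it."""
    phage = labels[labels.origin == "phage"]["read_id"]
    host = labels[labels.origin == "host"]["read_id"]
    recall = float(phage.isin(nonhost_ids).mean()) if len(phage) else 0.0
    leak = float(host.isin(nonhost_ids).mean()) if len(host) else 0.0
    return {"phage_recall": recall, "host_leakage": leak,
            "n_phage": int(len(phage)), "n_host": int(len(host))}


def de_performance(truth_de: pd.DataFrame, de_table: pd.DataFrame,
                   min_baseline_mean: float = 0.0,
                   baseline_means: pd.Series | None = None) -> dict[str, float]:
    """Recall of truth DE (gene, timepoint) pairs among significant calls and
    the false-positive count among null (gene, timepoint) pairs."""
    truth_set = {(r.gene, float(r.timepoint)) for r in truth_de.itertuples()}
    sig = de_table[de_table["significant"]]
    called = {(r.gene, float(r.timepoint)) for r in sig.itertuples()}
    tested = {(r.gene, float(r.timepoint)) for r in de_table.itertuples()}
    truth_tested = truth_set & tested
    if baseline_means is not None and min_baseline_mean > 0:
        strong = set(baseline_means[baseline_means >= min_baseline_mean].index)
        truth_tested = {(g, t) for g, t in truth_tested if g in strong}
    recall = (len(truth_tested & called) / len(truth_tested)
              if truth_tested else 0.0)
    fp = len(called - truth_set)
    return {"recall": recall, "false_positives": fp,
            "n_truth_tested": len(truth_tested), "n_significant": len(called)}
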