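#!/usr/bin/env python
"""Temporal classification of the recovered phage genes.

Prints the early/middle/late class summary (counts and percentages over all
predicted genes) and, via exact sequence matching to the simulator truth, the
class-assignment accuracy. Writes results/tables/class_summary.tsv and
class_accuracy.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from phagesub import evaluate as ev
from phagesub.annotate import GeneModel
from phagesub.seqs import read_fasta, read_gff3
from phagesub.simulate import load_truth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    ap.add_argument("--rundir", type=Path, default=ROOT / "results" / "pipeline")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    summary = pd.read_csv(args.rundir / "temporal" / "class_summary.tsv", sep="\t")
    summary.to_csv(args.outdir / "class_summary.tsv", sep="\t", index=False)
    print("temporal class summary (percent of all predicted genes):")
    print(summary.to_string(index=False))

    truth = load_truth(args.simdir)
    kept = read_fasta(args.rundir / "decontam" / "kept.fasta")
    genes = [GeneModel(f.attributes["ID"], f.seqid, f.start, f.end, f.strand)
             for f in read_gff3(args.rundir / "annotate" / "genes.gff3")]
    classes = pd.read_csv(args.rundir / "temporal" / "classes.tsv", sep="\t",
                          index_col=0)["class"]
    cr = ev.class_recovery(truth, classes, genes, kept)
    acc = pd.DataFrame([{"metric": "class_accuracy_pct",
                         "value": round(100 * cr["accuracy"], 2)},
                        {"metric": "n_genes_scored", "value": cr["n_scored"]}])
    acc.to_csv(args.outdir / "class_accuracy.tsv", sep="\t", index=False)
    print("\nvs simulator truth:")
    print(acc.to_string(index=False))


if __name__ == "__main__":
    main()
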