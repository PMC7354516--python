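"""Ground-truthed synthetic infection RNA-seq.

Emulates a bulk RNA-seq time course of phage-infected bacteria: a host genome
with annotated genes, an unknown AT-rich phage genome of non-overlapping
protein-coding genes, per-sample libraries whose host:phage read share decays
over the infection, class-structured phage temporal expression (early /
middle / late peak windows), a host differential-expression response, and
paired 150-nt reads with iid substitution errors. Every read pair carries an
origin label and the full truth (genomes, gene models, classes, DE table,
expected counts) is returned, so downstream stages can be scored exactly.

Two constructions make the truth unambiguous rather than merely likely:

* the phage and host genomes share no 31-mer (colliding windows are
  resampled), so read subtraction has a ground truth at the default k;
* phage coding regions are built from codons with periodic "stop-seed"
  blocks — short codon runs that place stop codons in all five non-coding
  frames while leaving the coding frame open — and intergenic gaps carry a
  six-frame stop spacer plus an in-frame stop just upstream of each start
  codon. Consequently the maximal-ORF scan recovers exactly the true gene
  coordinates and nothing else of comparable length.

Phage "transcripts" are the gene plus ~100 bp of flanking sequence (clamped
at the genome ends). Consecutive transcripts therefore overlap, emulating the
overlapping polycistronic transcription that lets an infection transcriptome
tile the whole phage genome — the property the subtractive-assembly approach
relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .kmers import kmer_codes
from .quant import SampleSpec
from .seqs import (GffFeature, ReadPair, revcomp, write_fasta,
                   write_fastq_pairs, write_gff3)

#: 12-mer containing stop codons in all six reading frames; embedded in every
#: intergenic gap so no open reading frame can cross it.
SIX_FRAME_STOP = "TTAATTAGTTAA"

#: codon block with stops in all frames except the coding frame (+0);
#: inserted periodically into simulated genes to suppress spurious ORFs.
STOP_SEED_BLOCK = ("TTA", "GTT", "AAT", "CAA")

_STOPS = {"TAA", "TAG", "TGA"}

#: the three infection experiments of the emulated study design:
#: duplicates at MOI 50, singletons at MOI 10, triplicates at MOI 50.
DEFAULT_DESIGN: dict[str, dict[float, int]] = {
    "exp1": {0.0: 2, 5.0: 2, 15.0: 2, 30.0: 2},
    "exp2": {33.0: 1, 45.0: 1, 63.0: 1, 75.0: 1, 92.0: 1},
    "exp3": {0.0: 3, 15.0: 3, 30.0: 3, 60.0: 3},
}
DEFAULT_MOI = {"exp1": 50.0, "exp2": 10.0, "exp3": 50.0}

#: host read share per minute post infection (free parameters of the
#: simulator; the study does not report read ratios)
DEFAULT_HOST_FRACTION = {0.0: 0.98, 5.0: 0.92, 15.0: 0.85, 30.0: 0.70,
                         33.0: 0.68, 45.0: 0.60, 60.0: 0.50, 63.0: 0.50,
                         75.0: 0.45, 92.0: 0.40}


@dataclass
class SimConfig:
    seed: int = 0
    host_length: int = 200_000
    host_gc: float = 0.47
    n_host_genes: int = 200
    phage_length: int = 50_000          # published YerA41 scale: 143_296
    phage_gc: float = 0.323
    n_phage_genes: int = 200
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"early": 0.25, "middle": 0.5, "late": 0.25})
    design: dict[str, dict[float, int]] = field(
        default_factory=lambda: {e: dict(d) for e, d in DEFAULT_DESIGN.items()})
    moi: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MOI))
    read_length: int = 150
    insert_mean: float = 220.0
    insert_sd: float = 30.0
    error_rate: float = 0.005
    library_size: int = 12_000          # read pairs per sample
    host_fraction_by_time: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_HOST_FRACTION))
    junk_fraction: float = 0.01
    de_truth: list[tuple[str, float, float]] | None = None  # (gene, tp, logFC)
    n_de_genes: int = 12                # used when de_truth is None
    transcript_ext: int = 100           # phage transcript flank, bp
    profile_baseline: float = 0.04      # off-window phage expression level
    amp_sigma: float = 0.5              # lognormal sigma of gene amplitudes
    degraded_tail_frac: float = 0.0     # fraction of mates given a low-Q 3' tail
    degraded_tail_len: int = 30
    quality_char: str = "F"             # Phred 37

    def __post_init__(self):
        s = sum(self.class_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1 (got {s})")
        if any(not (0 <= f <= 1) for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if not set(self.class_fractions) <= {"early", "middle", "late"}:
            raise ValueError("class_fractions keys must be early/middle/late")
        if not (0 < self.phage_gc < 1 and 0 < self.host_gc < 1):
            raise ValueError("GC fractions must lie in (0, 1)")
        for tps in self.design.values():
            for t in tps:
                if t not in self.host_fraction_by_time:
                    raise ValueError(f"no host fraction configured for t={t}")

    @property
    def timepoints(self) -> list[float]:
        return sorted({t for d in self.design.values() for t in d})

    def samples(self) -> list[SampleSpec]:
        """Deterministic sample order: experiment, timepoint, replicate."""
        out = []
        for exp in sorted(self.design):
            for tp in sorted(self.design[exp]):
                for rep in range(1, self.design[exp][tp] + 1):
                    name = f"{exp}_t{tp:g}_r{rep}"
                    out.append(SampleSpec(name, "", "", exp, tp, rep))
        return out

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    host_genome: str = ""
    phage_genome: str = ""
    host_genes: list[GeneModel] = field(default_factory=list)
    phage_genes: list[GeneModel] = field(default_factory=list)
    classes: dict[str, str] = field(default_factory=dict)        # phage gene -> class
    transcripts: dict[str, str] = field(default_factory=dict)    # gene -> transcript seq
    de_table: pd.DataFrame | None = None                         # gene, timepoint, logFC
    read_labels: dict[str, pd.DataFrame] = field(default_factory=dict)
    expected_counts: pd.DataFrame | None = None                  # genes x samples

    def gene_seq(self, g: GeneModel) -> str:
        genome = self.phage_genome if g.id.startswith("pg") else self.host_genome
        return g.extract(genome)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """n random non-stop codons with iid bases at the given GC."""
    out: list[str] = []
    while len(out) < n:
        chunk = _random_bases(rng, 3 * (n - len(out) + 4), gc)
        for i in range(0, len(chunk) - 2, 3):
            c = chunk[i:i + 3]
            if c not in _STOPS:
                out.append(c)
                if len(out) == n:
                    break
    return out


def _build_orf(rng: np.random.Generator, n_codons: int, gc: float,
               seed_every: int = 8) -> str:
    """Start codon + interior codons with periodic stop-seed blocks + stop."""
    start = rng.choice(["ATG", "GTG", "TTG"], p=[0.8, 0.15, 0.05])
    stop = rng.choice(["TAA", "TGA", "TAG"], p=[0.5, 0.3, 0.2])
    interior = n_codons - 2
    cods: list[str] = []
    n_rand = 0
    while len(cods) < interior:
        cods.append(_random_codons(rng, 1, gc)[0])
        n_rand += 1
        if n_rand % seed_every == 0 and len(cods) + len(STOP_SEED_BLOCK) <= interior:
            cods.extend(STOP_SEED_BLOCK)
    return start + "".join(cods[:interior]) + stop


def _class_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the classes."""
    names = list(fractions)
    raw = {c: n * fractions[c] for c in names}
    counts = {c: math.floor(raw[c]) for c in names}
    rem = n - sum(counts.values())
    for c in sorted(names, key=lambda c: (-(raw[c] - counts[c]), names.index(c)))[:rem]:
        counts[c] += 1
    return counts


def simulate_genomes(config: SimConfig,
                     rng: np.random.Generator | None = None) -> SimTruth:
    """Host genome with gene intervals plus a phage genome of real ORFs.

    The phage is laid out left to right as [gap | six-frame stop spacer |
    RBS cassette | ORF] units; gaps absorb the length budget so the genome is
    exactly ``phage_length``. Phage windows sharing a 31-mer with the host are
    resampled. Raises when the genes cannot fit the genome.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    k_guard = 31
    if config.phage_length < 10 * k_guard or config.host_length < 10 * k_guard:
        raise ValueError("genome lengths must be >= 10x the guard k-mer size")
    truth = SimTruth()

    # --- host: random genome, genes are intervals -------------------------
    truth.host_genome = _random_bases(rng, config.host_length, config.host_gc)
    gene_len = rng.integers(500, 1201, size=config.n_host_genes)
    min_gap = 20
    space = config.host_length - int(gene_len.sum()) - min_gap * (config.n_host_genes + 1)
    if space < 0:
        raise ValueError("host genes do not fit the host genome")
    extra = rng.multinomial(space, np.full(config.n_host_genes + 1,
                                           1 / (config.n_host_genes + 1)))
    pos = 0
    width = max(3, len(str(config.n_host_genes)))
    for i in range(config.n_host_genes):
        pos += min_gap + int(extra[i])
        start = pos + 1
        end = pos + int(gene_len[i])
        strand = "+" if rng.random() < 0.5 else "-"
        truth.host_genes.append(GeneModel(f"hg{i + 1:0{width}d}", "host", start, end, strand))
        pos = end

    # --- phage: ORF cassettes ---------------------------------------------
    n = config.n_phage_genes
    codons = rng.integers(38, 86, size=n)           # gene lengths 114..255 bp
    gaps = rng.integers(6, 40, size=n)              # random part of each gap
    cassette_fixed = len(SIX_FRAME_STOP) + 6 + 5 + 3  # spacer + AGGAGG + pad + TAA
    fixed = int(3 * codons.sum()) + int(gaps.sum()) + n * cassette_fixed
    leftover = config.phage_length - fixed - 40     # keep a short random tail
    if leftover < 0:
        raise ValueError(
            f"{n} phage genes (~{fixed} bp) do not fit phage_length="
            f"{config.phage_length}")
    gaps = gaps + rng.multinomial(leftover, np.full(n, 1 / n))

    counts = _class_counts(n, config.class_fractions)
    order = [c for c in ("early", "middle", "late") if c in counts]
    class_of = []
    for c in order:
        class_of.extend([c] * counts[c])

    genic_gc = 0.40  # interior-codon base GC; global GC fixed up via gaps below
    parts: list[str] = []
    gene_spans: list[tuple[int, int, str]] = []  # 0-based ORF span + strand
    pos = 0
    gap_slots: list[tuple[int, int]] = []        # purely random stretches, safe to flip
    for i in range(n):
        gap = _random_bases(rng, int(gaps[i]), config.phage_gc)
        half = len(gap) // 2
        gap = gap[:half] + SIX_FRAME_STOP + gap[half:]
        orf = _build_orf(rng, int(codons[i]), genic_gc)
        pad = _random_bases(rng, 5, genic_gc)
        cassette = "AGGAGG" + pad + "TAA" + orf
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            unit = gap + revcomp(cassette)
            orf_lo = pos + len(gap)                       # revcomp(orf) sits first
            gene_spans.append((orf_lo, orf_lo + len(orf), "-"))
        else:
            unit = gap + cassette
            orf_lo = pos + len(gap) + 14
            gene_spans.append((orf_lo, orf_lo + len(orf), "+"))
        gap_slots.append((pos, pos + half))
        gap_slots.append((pos + half + len(SIX_FRAME_STOP), pos + len(gap)))
        parts.append(unit)
        pos += len(unit)
    tail = config.phage_length - pos
    parts.append(_random_bases(rng, tail, config.phage_gc))
    gap_slots.append((pos, pos + tail))
    phage = "".join(parts)

    # --- pull overall GC onto the target by resampling free gap bases -----
    phage = _retarget_gc(rng, phage, config.phage_gc, gap_slots)

    # --- guarantee k-mer disjointness from the host ------------------------
    phage = _resolve_collisions(rng, phage, truth.host_genome, gene_spans,
                                k_guard, genic_gc, config.phage_gc)

    truth.phage_genome = phage
    width = max(3, len(str(n)))
    for i, (lo, hi, strand) in enumerate(gene_spans):
        gid = f"pg{i + 1:0{width}d}"
        truth.phage_genes.append(GeneModel(gid, "phage", lo + 1, hi, strand))
        truth.classes[gid] = class_of[i]

    # transcripts: gene plus flanks, clamped; first/last reach the genome ends
    ext = config.transcript_ext
    for i, g in enumerate(truth.phage_genes):
        lo = 0 if i == 0 else max(0, g.start - 1 - ext)
        hi = len(phage) if i == len(truth.phage_genes) - 1 else min(len(phage), g.end + ext)
        truth.transcripts[g.id] = phage[lo:hi]
    for g in truth.host_genes:
        truth.transcripts[g.id] = truth.host_genome[g.start - 1:g.end]
    return truth


def _retarget_gc(rng: np.random.Generator, genome: str, target: float,
                 free_slots: list[tuple[int, int]]) -> str:
    """Flip bases within the free (purely random, intergenic) stretches so
    the overall GC lands on the target; ORFs, RBS cassettes and stop spacers
    are never touched."""
    free_mask = np.zeros(len(genome), dtype=bool)
    for lo, hi in free_slots:
        free_mask[lo:hi] = True
    seq = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    need = round(target * len(genome)) - int(is_gc.sum())
    free = np.flatnonzero(free_mask)
    if need > 0:
        cand = free[~is_gc[free]]
        flip = rng.choice(cand, size=min(need, len(cand)), replace=False)
        seq[flip] = np.where(rng.random(len(flip)) < 0.5, ord("G"), ord("C"))
    elif need < 0:
        cand = free[is_gc[free]]
        flip = rng.choice(cand, size=min(-need, len(cand)), replace=False)
        seq[flip] = np.where(rng.random(len(flip)) < 0.5, ord("A"), ord("T"))
    return seq.tobytes().decode()


def _resolve_collisions(rng: np.random.Generator, phage: str, host: str,
                        gene_spans, k: int, genic_gc: float,
                        inter_gc: float, max_rounds: int = 20) -> str:
    """Resample any phage window sharing a canonical k-mer with the host."""
    host_set = set(np.unique(kmer_codes(host, k)).tolist())
    for _ in range(max_rounds):
        codes = kmer_codes(phage, k).tolist()
        bad = [i for i, c in enumerate(codes) if c in host_set]
        if not bad:
            return phage
        seq = list(phage)
        for i in bad:
            span = next(((lo, hi, st) for lo, hi, st in gene_spans
                         if lo < i + k and hi > i), None)
            if span is None:
                for j in range(i, min(i + k, len(seq))):
                    seq[j] = "ACGT"[rng.integers(0, 4)]
            else:
                lo, hi, strand = span
                # re-roll one codon-aligned interior triplet inside the gene
                j = max(0, (max(i, lo) - lo) // 3)
                rel = min(max(lo + 3 * j, lo + 3), hi - 6)
                cod = _random_codons(rng, 1, genic_gc)[0]
                seq[rel:rel + 3] = list(cod if strand == "+" else revcomp(cod))
        phage = "".join(seq)
    raise RuntimeError("could not remove host/phage k-mer collisions")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_PROFILE_ANCHORS = {
    "early": [(0.0, 0.3), (5.0, 1.0), (15.0, 1.0), (33.0, None), (1e9, None)],
    "middle": [(0.0, None), (15.0, None), (33.0, 1.0), (45.0, 1.0),
               (63.0, None), (1e9, None)],
    "late": [(0.0, None), (45.0, None), (63.0, 1.0), (92.0, 1.0), (1e9, 1.0)],
}


def class_profile(cls: str, t: float, baseline: float) -> float:
    """Piecewise-linear temporal profile: rise to the peak window, decay after,
    never below the baseline."""
    anchors = [(x, baseline if v is None else v) for x, v in _PROFILE_ANCHORS[cls]]
    xs = [a for a, _ in anchors]
    ys = [b for _, b in anchors]
    return float(np.interp(t, xs, ys))


def default_de_truth(truth: SimTruth, config: SimConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Pick host DE genes and effect sizes: each gene switches at an onset
    timepoint and keeps its logFC afterwards."""
    tps = [t for t in config.timepoints if t > 0]
    onsets = [t for t in (15.0, 30.0, 60.0) if t in tps] or tps[:1]
    ids = [g.id for g in truth.host_genes]
    chosen = rng.choice(len(ids), size=min(config.n_de_genes, len(ids)), replace=False)
    rows = []
    for gi in sorted(chosen.tolist()):
        lfc = float(rng.choice([-3.0, -2.0, -1.5, 1.5, 2.0, 3.0]))
        onset = float(rng.choice(onsets))
        for t in tps:
            if t >= onset:
                rows.append({"gene": ids[gi], "timepoint": t, "logFC": lfc})
    return pd.DataFrame(rows)


def simulate_expression(truth: SimTruth, config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Relative transcript abundances (transcripts x samples; columns sum 1).

    Host transcripts share host_fraction(t) of each library, phage transcripts
    1 - host_fraction(t) - junk_fraction, and a ``__junk__`` row absorbs the
    rest. Phage genes follow their class profile times a lognormal amplitude;
    host DE genes shift by 2**logFC at their truth timepoints.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    for g in truth.phage_genes:
        if g.id not in truth.classes:
            raise ValueError(f"phage gene {g.id} lacks a class label")
    if truth.de_table is None:
        truth.de_table = (default_de_truth(truth, config, rng)
                          if config.de_truth is None
                          else pd.DataFrame(config.de_truth,
                                            columns=["gene", "timepoint", "logFC"]))
    de = {(r.gene, float(r.timepoint)): float(r.logFC)
          for r in truth.de_table.itertuples()}

    host_ids = [g.id for g in truth.host_genes]
    phage_ids = [g.id for g in truth.phage_genes]
    host_base = np.exp(rng.normal(0.0, 1.0, size=len(host_ids)))
    phage_amp = np.exp(rng.normal(0.0, config.amp_sigma, size=len(phage_ids)))

    cols = {}
    b = config.profile_baseline
    for s in config.samples():
        t = s.timepoint_min
        if t not in config.host_fraction_by_time:
            raise ValueError(f"timepoint {t} missing from host_fraction_by_time")
        hf = config.host_fraction_by_time[t]
        host = host_base * np.array([2.0 ** de.get((g, t), 0.0) for g in host_ids])
        host = host / host.sum() * hf
        phage = phage_amp * np.array(
            [class_profile(truth.classes[g], t, b) for g in phage_ids])
        phage = phage / phage.sum() * (1.0 - hf - config.junk_fraction)
        cols[s.name] = np.concatenate([host, phage, [config.junk_fraction]])
    abund = pd.DataFrame(cols, index=host_ids + phage_ids + ["__junk__"])
    return abund


def expected_counts(abund: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Noise-free expected pair counts per transcript and sample."""
    return abund.drop(index="__junk__") * config.library_size


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, n_err: int) -> str:
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=min(n_err, len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        cur = out[p]
        alts = [b for b in "ACGT" if b != cur]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def simulate_sample_reads(sample: SampleSpec, abund_col: pd.Series,
                          truth: SimTruth, config: SimConfig,
                          rng: np.random.Generator,
                          rng_err: np.random.Generator | None = None
                          ) -> tuple[list[ReadPair], pd.DataFrame]:
    """All read pairs for one sample plus their origin-label table.

    Errors are drawn from a separate stream (``rng_err``) so the same seed
    yields identical fragments at any error rate.
    """
    if rng_err is None:
        rng_err = np.random.default_rng(rng.integers(2 ** 31))
    n = config.library_size
    names = list(abund_col.index)
    p = abund_col.to_numpy(dtype=float)
    draws = rng.multinomial(n, p / p.sum()) if n > 0 else np.zeros(len(p), int)
    rl = config.read_length
    pairs: list[ReadPair] = []
    labels: list[tuple[str, str, str]] = []
    idx = 0
    for tname, m in zip(names, draws.tolist()):
        if m == 0:
            continue
        if tname == "__junk__":
            origin = "junk"
            tseq = None
            tlen = 2 * rl
        else:
            origin = "host" if tname.startswith("hg") else "phage"
            tseq = truth.transcripts[tname]
            tlen = len(tseq)
        ins = np.clip(np.rint(rng.normal(config.insert_mean, config.insert_sd, m)),
                      min(60, tlen), tlen).astype(int)
        starts = (rng.random(m) * (tlen - ins + 1)).astype(int)
        errs = rng_err.binomial(np.minimum(ins, rl)[:, None], config.error_rate,
                                size=(m, 2))
        flips = rng.random(m) < 0.5
        for j in range(m):
            if tseq is None:
                frag = _random_bases(rng, int(ins[j]), 0.5)
            else:
                frag = tseq[starts[j]:starts[j] + ins[j]]
            mlen = min(rl, len(frag))
            r1 = _mutate(rng_err, frag[:mlen], int(errs[j, 0]))
            r2 = _mutate(rng_err, revcomp(frag)[:mlen], int(errs[j, 1]))
            if flips[j]:
                r1, r2 = r2, r1
            rid = f"{sample.name}_p{idx:06d}"
            idx += 1
            q1, q2 = config.quality_char * len(r1), config.quality_char * len(r2)
            if config.degraded_tail_frac > 0:
                tl = config.degraded_tail_len
                if rng_err.random() < config.degraded_tail_frac and len(q1) > tl:
                    q1 = q1[:-tl] + "#" * tl
                if rng_err.random() < config.degraded_tail_frac and len(q2) > tl:
                    q2 = q2[:-tl] + "#" * tl
            pairs.append(ReadPair(rid, r1, q1, r2, q2))
            labels.append((rid, origin, tname))
    perm = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in perm]
    labels = [labels[i] for i in perm]
    lab = pd.DataFrame(labels, columns=["read_id", "origin", "transcript"])
    return pairs, lab


def simulate_reads(truth: SimTruth, abund: pd.DataFrame, config: SimConfig,
                   outdir: str | Path | None = None
                   ) -> tuple[list[SampleSpec], dict[str, list[ReadPair]]]:
    """Reads for every sample; optionally written as paired FASTQ files.

    Returns the sample sheet (fastq paths filled in when outdir is given) and
    the in-memory pairs per sample. Per-pair origin labels land in
    ``truth.read_labels``.
    """
    samples = config.samples()
    ss = np.random.SeedSequence(config.seed).spawn(3)[2].spawn(len(samples))
    all_pairs: dict[str, list[ReadPair]] = {}
    for s, child in zip(samples, ss):
        rng = np.random.default_rng(child)
        pairs, labels = simulate_sample_reads(s, abund[s.name], truth, config, rng)
        all_pairs[s.name] = pairs
        truth.read_labels[s.name] = labels
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            s.fastq1 = str(outdir / f"{s.name}_1.fastq")
            s.fastq2 = str(outdir / f"{s.name}_2.fastq")
            write_fastq_pairs(s.fastq1, s.fastq2, pairs)
    return samples, all_pairs


def simulate_all(config: SimConfig, outdir: str | Path | None = None
                 ) -> tuple[SimTruth, pd.DataFrame, list[SampleSpec],
                            dict[str, list[ReadPair]]]:
    """Genomes -> expression -> reads, with optional on-disk artifacts."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    truth = simulate_genomes(config, np.random.default_rng(ss[0]))
    abund = simulate_expression(truth, config, np.random.default_rng(ss[1]))
    truth.expected_counts = expected_counts(abund, config)
    samples, pairs = simulate_reads(truth, abund, config, outdir)
    if outdir is not None:
        write_truth(truth, config, samples, Path(outdir))
    return truth, abund, samples, pairs


def load_truth(simdir: str | Path) -> SimTruth:
    """Rebuild a SimTruth (genomes, gene models, classes, DE table, expected
    counts) from the files written by :func:`write_truth`."""
    from .seqs import read_fasta, read_gff3
    simdir = Path(simdir)
    truth = SimTruth()
    truth.host_genome = read_fasta(simdir / "host.fasta")["host"]
    truth.phage_genome = read_fasta(simdir / "phage_truth.fasta")["phage"]
    for f in read_gff3(simdir / "host_genes.gff3"):
        truth.host_genes.append(GeneModel(f.attributes["ID"], "host",
                                          f.start, f.end, f.strand))
    for f in read_gff3(simdir / "phage_truth_genes.gff3"):
        gid = f.attributes["ID"]
        truth.phage_genes.append(GeneModel(gid, "phage", f.start, f.end, f.strand))
        truth.classes[gid] = f.attributes["temporal_class"]
    de_path = simdir / "host_de_truth.tsv"
    if de_path.exists():
        truth.de_table = pd.read_csv(de_path, sep="\t")
    ec = simdir / "expected_counts.tsv"
    if ec.exists():
        truth.expected_counts = pd.read_csv(ec, sep="\t", index_col=0)
    return truth


def write_truth(truth: SimTruth, config: SimConfig,
                samples: list[SampleSpec], outdir: Path) -> None:
    """FASTA genomes, GFF3 gene models, truth tables, sample sheet, config echo."""
    import yaml
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "host.fasta", [("host", truth.host_genome)])
    write_fasta(outdir / "phage_truth.fasta", [("phage", truth.phage_genome)])
    write_gff3(outdir / "host_genes.gff3",
               [GffFeature("host", "gene", g.start, g.end, g.strand, {"ID": g.id})
                for g in truth.host_genes])
    write_gff3(outdir / "phage_truth_genes.gff3",
               [GffFeature("phage", "gene", g.start, g.end, g.strand,
                           {"ID": g.id, "temporal_class": truth.classes[g.id]})
                for g in truth.phage_genes])
    pd.DataFrame([{"gene": g, "class": c} for g, c in truth.classes.items()]
                 ).to_csv(outdir / "phage_classes.tsv", sep="\t", index=False)
    if truth.de_table is not None:
        truth.de_table.to_csv(outdir / "host_de_truth.tsv", sep="\t", index=False)
    if truth.expected_counts is not None:
        truth.expected_counts.to_csv(outdir / "expected_counts.tsv", sep="\t")
    labs = pd.concat([df.assign(sample=s) for s, df in truth.read_labels.items()],
                     ignore_index=True)
    labs.to_csv(outdir / "read_labels.tsv", sep="\t", index=False)
    pd.DataFrame([{"sample": s.name, "fastq1": s.fastq1, "fastq2": s.fastq2,
                   "experiment": s.experiment, "timepoint_min": s.timepoint_min,
                   "replicate": s.replicate} for s in samples]
                 ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)
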