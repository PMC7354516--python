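"""Simulator contracts: determinism, composition, layout, labels, expression."""

import math

import numpy as np
import pytest

from phagesub.seqs import gc_content, revcomp
from phagesub.simulate import (SimConfig, simulate_genomes, simulate_all,
                               class_profile)

SMALL = dict(host_length=30_000, n_host_genes=20, phage_length=6_000,
             n_phage_genes=20, library_size=400)


def test_identical_seed_and_config_reproduce_outputs_exactly():
    a = simulate_all(SimConfig(seed=42, **SMALL))
    b = simulate_all(SimConfig(seed=42, **SMALL))
    assert a[0].phage_genome == b[0].phage_genome
    assert a[0].host_genome == b[0].host_genome
    assert a[1].equals(b[1])
    for name in a[3]:
        assert [(p.id, p.seq1, p.qual1, p.seq2, p.qual2) for p in a[3][name]] == \
               [(p.id, p.seq1, p.qual1, p.seq2, p.qual2) for p in b[3][name]]
    c = simulate_all(SimConfig(seed=43, **SMALL))
    assert c[0].phage_genome != a[0].phage_genome


def test_phage_gc_within_binomial_bound():
    cfg = SimConfig(seed=7, phage_length=50_000, phage_gc=0.32,
                    host_length=60_000, n_host_genes=40, n_phage_genes=150)
    truth = simulate_genomes(cfg)
    sd = math.sqrt(0.32 * 0.68 / 50_000)
    assert abs(gc_content(truth.phage_genome) - 0.32) <= 3 * sd


def test_published_scale_genome_has_exact_length():
    cfg = SimConfig(seed=1, phage_length=143_296, phage_gc=0.323,
                    host_length=80_000, n_host_genes=40, n_phage_genes=201)
    truth = simulate_genomes(cfg)
    assert len(truth.phage_genome) == 143_296
    assert abs(gc_content(truth.phage_genome) - 0.323) < 0.01


def test_gene_layout_disjoint_with_gaps():
    truth = simulate_genomes(SimConfig(seed=9, **SMALL))
    spans = sorted((g.start, g.end) for g in truth.phage_genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 - 1 >= 20  # intergenic gap
    assert spans[0][0] >= 1 and spans[-1][1] <= 6_000
    # genes are genuine ORFs on their strands
    for g in truth.phage_genes:
        cds = truth.gene_seq(g)
        assert cds[:3] in ("ATG", "GTG", "TTG") and cds[-3:] in ("TAA", "TAG", "TGA")
        assert len(cds) % 3 == 0


def test_phage_and_host_share_no_31mer():
    truth = simulate_genomes(SimConfig(seed=13, **SMALL))
    from phagesub.kmers import kmer_codes
    host = set(np.unique(kmer_codes(truth.host_genome, 31)).tolist())
    phage = set(np.unique(kmer_codes(truth.phage_genome, 31)).tolist())
    assert not (host & phage)


def test_impossible_layout_raises():
    with pytest.raises(ValueError):
        simulate_genomes(SimConfig(seed=1, host_length=30_000, n_host_genes=20,
                                   phage_length=2_000, n_phage_genes=50))
    with pytest.raises(ValueError):
        SimConfig(class_fractions={"early": 0.7, "middle": 0.7, "late": -0.4})


def test_expression_postconditions(micro_sim):
    cfg, truth, abund, samples, pairs = micro_sim
    # columns are proper compositions
    assert np.allclose(abund.sum(axis=0), 1.0)
    # each gene's window-mean abundance peaks in its own class window
    tps = {s.name: s.timepoint_min for s in samples}
    windows = {"early": (5.0, 15.0), "middle": (33.0, 45.0),
               "late": (63.0, 75.0, 92.0)}
    cols_by_tp = {}
    for name, t in tps.items():
        cols_by_tp.setdefault(t, []).append(name)
    for g in truth.phage_genes:
        means = {}
        for cls, wtps in windows.items():
            cols = [c for t in wtps for c in cols_by_tp[t]]
            means[cls] = abund.loc[g.id, cols].mean()
        assert max(means, key=means.get) == truth.classes[g.id]


def test_host_de_shift_matches_truth_logfc(micro_sim):
    cfg, truth, abund, samples, pairs = micro_sim
    entry = truth.de_table.iloc[0]
    gene, tp, lfc = entry.gene, float(entry.timepoint), float(entry.logFC)
    s_t = next(s.name for s in samples if s.timepoint_min == tp)
    s_0 = next(s.name for s in samples if s.timepoint_min == 0.0)
    hf = cfg.host_fraction_by_time
    # compare within-host relative abundance, correcting for the host share
    others = [g.id for g in truth.host_genes
              if g.id not in set(truth.de_table.gene)]
    rel_t = abund.loc[gene, s_t] / abund.loc[others, s_t].sum()
    rel_0 = abund.loc[gene, s_0] / abund.loc[others, s_0].sum()
    assert rel_t / rel_0 == pytest.approx(2.0 ** lfc, rel=1e-6)


def test_class_profile_shape():
    b = 0.04
    assert class_profile("early", 10.0, b) == 1.0
    assert class_profile("early", 92.0, b) == b
    assert class_profile("middle", 40.0, b) == 1.0
    assert class_profile("late", 75.0, b) == 1.0
    assert class_profile("late", 5.0, b) == b


def test_read_labels_conserve_library_and_host_fraction(micro_sim):
    cfg, truth, abund, samples, pairs = micro_sim
    for s in samples:
        labels = truth.read_labels[s.name]
        assert len(labels) == cfg.library_size == len(pairs[s.name])
        hf = cfg.host_fraction_by_time[s.timepoint_min]
        frac = (labels.origin == "host").mean()
        sd = math.sqrt(hf * (1 - hf) / cfg.library_size)
        assert abs(frac - hf) <= 3.5 * sd


def test_error_free_reads_are_exact_substrings(errorfree_sim):
    cfg, truth, abund, samples, pairs = errorfree_sim
    checked = 0
    for s in samples[:3]:
        labels = truth.read_labels[s.name].set_index("read_id")
        for p in pairs[s.name][:50]:
            t = truth.transcripts[labels.loc[p.id, "transcript"]]
            for seq in (p.seq1, p.seq2):
                assert seq in t or revcomp(seq) in t
            checked += 1
    assert checked > 100


def test_error_rate_matches_binomial_expectation():
    cfg = SimConfig(seed=99, error_rate=0.01, **SMALL)
    truth, abund, samples, pairs = simulate_all(cfg)
    cfg0 = SimConfig(seed=99, error_rate=0.0, **SMALL)
    truth0, abund0, samples0, pairs0 = simulate_all(cfg0)
    # same seeds => same fragments; mismatches are exactly the injected errors
    n_mm = n_bases = 0
    for s in samples:
        for p, q in zip(pairs[s.name], pairs0[s.name]):
            for a, b in ((p.seq1, q.seq1), (p.seq2, q.seq2)):
                n_mm += sum(x != y for x, y in zip(a, b))
                n_bases += len(a)
            if n_bases >= 10_000 * 150:
                break
        if n_bases >= 10_000 * 150:
            break
    rate = n_mm / n_bases
    sd = math.sqrt(0.01 * 0.99 / n_bases)
    assert abs(rate - 0.01) <= 4 * sd


def test_zero_library_size_yields_empty_valid_sample():
    cfg = SimConfig(seed=3, library_size=0, **{k: v for k, v in SMALL.items()
                                               if k != "library_size"})
    truth, abund, samples, pairs = simulate_all(cfg)
    assert all(len(v) == 0 for v in pairs.values())
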