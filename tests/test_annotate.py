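"""ORF calling and RBS scoring against naive oracles."""

import pytest
from Bio.Seq import Seq

from phagesub.annotate import (find_orfs, score_rbs, call_genes,
                               START_CODONS, STOP_CODONS)
from phagesub.seqs import revcomp
from phagesub.simulate import SimConfig, simulate_genomes


def oracle_orfs(seq, min_codons, starts=START_CODONS, stops=STOP_CODONS):
    """Naive six-frame scan: per stop codon, the first start after the
    previous in-frame stop."""
    res = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for f in range(3):
            boundary = f
            for sp in range(f, n - 2, 3):
                if s[sp:sp + 3] not in stops:
                    continue
                st = None
                for j in range(boundary, sp, 3):
                    if s[j:j + 3] in starts:
                        st = j
                        break
                if st is not None and sp + 3 - st >= 3 * min_codons:
                    if strand == "+":
                        res.append((st + 1, sp + 3, "+"))
                    else:
                        res.append((n - (sp + 3) + 1, n - st, "-"))
                boundary = sp + 3
    return sorted(res)


def oracle_rbs(window, dist_to_start, motif="AGGAGGT"):
    best = (0, -1)
    for ln in range(1, len(motif) + 1):
        for ms in range(len(motif) - ln + 1):
            sub = motif[ms:ms + ln]
            start = 0
            while True:
                pos = window.find(sub, start)
                if pos == -1:
                    break
                spacer = len(window) - (pos + ln) + dist_to_start
                if ln > best[0] or (ln == best[0] and spacer < best[1]):
                    best = (ln, spacer)
                start = pos + 1
    return best


def test_minimal_orf_hand_example():
    assert find_orfs("ATGAAATAA", min_codons=2) == [(1, 9, "+")]


def test_reverse_complement_gives_minus_strand_orf():
    assert find_orfs(revcomp("ATGAAATAA"), min_codons=2) == [(1, 9, "-")]


def test_orf_scan_matches_naive_oracle_on_random_sequence(rng):
    seq = "".join(rng.choice(list("ACGT"), 10_000, p=[0.34, 0.16, 0.16, 0.34]))
    assert find_orfs(seq, min_codons=20) == oracle_orfs(seq, 20)


def test_same_stop_orfs_resolve_to_longest():
    # two in-frame starts share one stop: only the longer ORF is emitted
    seq = "ATGAAAATGAAATAA"
    assert find_orfs(seq, min_codons=2) == [(1, 15, "+")]


def test_input_validation():
    with pytest.raises(ValueError):
        find_orfs("ATGXXXTAA", min_codons=2)
    with pytest.raises(ValueError):
        find_orfs("ATGAAATAA", min_codons=1)


def test_rbs_worked_example():
    seq = "C" * 16 + "AGGAGG" + "C" * 8 + "ATGAAATAA"
    score, spacer = score_rbs(seq, 31, 39, "+")
    assert (score, spacer) == (6, 8)


def test_rbs_all_c_window_scores_zero():
    seq = "C" * 30 + "ATGAAATAA"
    assert score_rbs(seq, 31, 39, "+")[0] == 0


def test_rbs_matches_exhaustive_oracle(rng):
    for _ in range(50):
        up = "".join(rng.choice(list("ACGT"), 17))
        seq = "C" * 3 + up + "CCC" + "ATGAAATAA"
        start = len(seq) - 8
        got = score_rbs(seq, start, len(seq), "+")
        assert got == oracle_rbs(up, 3)


def test_rbs_strand_symmetry(rng):
    seq = "C" * 4 + "".join(rng.choice(list("ACGT"), 17)) + "CCC" + "ATGAAATAA"
    start = len(seq) - 8
    plus = score_rbs(seq, start, len(seq), "+")
    rc = revcomp(seq)
    minus = score_rbs(rc, 1, 9 + 0, "-")  # gene mirrored to the rc start
    # coordinates of the mirrored gene: start..end = 1..9 on the rc sequence
    assert minus == plus


def test_truth_genes_recovered_exactly_with_high_precision():
    cfg = SimConfig(seed=7, host_length=30_000, n_host_genes=20,
                    phage_length=8_000, n_phage_genes=30)
    truth = simulate_genomes(cfg)
    genes = call_genes({"phage": truth.phage_genome})
    called = {(g.start, g.end, g.strand) for g in genes}
    expected = {(g.start, g.end, g.strand) for g in truth.phage_genes}
    assert expected <= called
    assert len(expected & called) / len(called) >= 0.9


def test_annotating_reverse_complement_mirrors_genes():
    cfg = SimConfig(seed=3, host_length=30_000, n_host_genes=20,
                    phage_length=6_000, n_phage_genes=20)
    truth = simulate_genomes(cfg)
    seq = truth.phage_genome
    fwd = call_genes({"s": seq})
    rev = call_genes({"s": revcomp(seq)})
    n = len(seq)
    mirrored = {(n - g.end + 1, n - g.start + 1, "-" if g.strand == "+" else "+")
                for g in rev}
    assert {(g.start, g.end, g.strand) for g in fwd} == mirrored
    # RBS scores are strand-symmetric too
    fwd_scores = sorted(g.rbs_score for g in fwd)
    rev_scores = sorted(g.rbs_score for g in rev)
    assert fwd_scores == rev_scores


def test_called_genes_translate_without_internal_stop():
    cfg = SimConfig(seed=5, host_length=30_000, n_host_genes=20,
                    phage_length=5_000, n_phage_genes=18)
    truth = simulate_genomes(cfg)
    scaffs = {"phage": truth.phage_genome}
    for g in call_genes(scaffs):
        cds = g.extract(scaffs[g.scaffold])
        assert len(cds) % 3 == 0
        assert cds[:3] in START_CODONS and cds[-3:] in STOP_CODONS
        aa = str(Seq(cds[:-3]).translate(table=11))
        assert "*" not in aa


def test_low_rbs_gene_gets_low_confidence():
    seq = "C" * 30 + "ATG" + "AAA" * 40 + "TAA"
    genes = call_genes({"s": seq})
    assert len(genes) == 1 and genes[0].confidence == "low"
    seq2 = "C" * 16 + "AGGAGG" + "C" * 8 + "ATG" + "AAA" * 40 + "TAA"
    genes2 = call_genes({"s": seq2})
    assert genes2[0].confidence == "high" and genes2[0].rbs_score >= 4
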