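"""De Bruijn assembly against brute-force string oracles."""

import numpy as np
import pytest

from phagesub.assemble import (build_graph, prune, pop_bubbles,
                               extract_unitigs, scaffold_contigs,
                               assembly_stats, stats_from_rows, Scaffold)
from phagesub.datasets import YERA41_SCAFFOLDS
from phagesub.kmers import kmer_codes, decode_kmer
from phagesub.seqs import ReadPair, revcomp


# ---------------------------------------------------------------------------
# string-based oracle for the bidirected k-mer graph
# ---------------------------------------------------------------------------

def canon(w):
    return min(w, revcomp(w))


def oracle_nodes(seqs, k, min_count=1):
    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = canon(s[i:i + k])
            counts[w] = counts.get(w, 0) + 1
    return {w: c for w, c in counts.items() if c >= min_count}


def oracle_unitigs(nodes, k):
    """Maximal non-branching paths over the string node set."""
    def succ(w):
        return [w[1:] + b for b in "ACGT" if canon(w[1:] + b) in nodes]

    def pred(w):
        return [b + w[:-1] for b in "ACGT" if canon(b + w[:-1]) in nodes]

    visited, out = set(), []
    for start in sorted(nodes):
        if start in visited:
            continue
        path = [start]
        seen = {start}
        for direction in (1, 0):
            while True:
                cur = path[-1] if direction else path[0]
                nxt = succ(cur) if direction else pred(cur)
                if len(nxt) != 1:
                    break
                y = nxt[0]
                back = pred(y) if direction else succ(y)
                if len(back) != 1:
                    break
                if canon(y) in seen or canon(y) in visited:
                    break
                seen.add(canon(y))
                path.append(y) if direction else path.insert(0, y)
        visited.update(canon(w) for w in path)
        seq = path[0] + "".join(w[-1] for w in path[1:])
        out.append(canon(seq))
    return sorted(out, key=lambda s: (-len(s), s))


def oracle_edges(nodes, k):
    """Distinct undirected (k-1)-overlap adjacencies between retained nodes."""
    edges = set()
    for w in nodes:
        for v in (w, revcomp(w)):
            for b in "ACGT":
                y = v[1:] + b
                if canon(y) in nodes:
                    edges.add(frozenset((canon(v), canon(y))))
    return edges


# ---------------------------------------------------------------------------

def test_graph_from_single_read_matches_hand_enumeration():
    g = build_graph(["ACGTACG"], 5, min_count=1)
    expect = oracle_nodes(["ACGTACG"], 5)
    got = {decode_kmer(c, 5) for c in g.counts}
    assert got == set(expect)
    # the two read-consecutive adjacencies are present
    assert g.n_edges() == len(oracle_edges(set(expect), 5))


def test_min_count_drops_singleton_error_kmers(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    mutated = seq[:100] + ("A" if seq[100] != "A" else "C") + seq[101:]
    reads = [seq] * 30 + [mutated]
    g = build_graph(reads, 31, min_count=2)
    clean = oracle_nodes([seq], 31)
    got = {decode_kmer(c, 31) for c in g.counts}
    assert got == set(clean)


def test_empty_input_gives_empty_graph():
    assert len(build_graph([], 31)) == 0
    assert extract_unitigs(build_graph([], 31)) == []


def test_prune_removes_low_coverage_tip_and_is_idempotent(rng):
    seq = "".join(rng.choice(list("ACGT"), 300))
    # substitution at the last base of a short read: a one-node dead-end branch
    flip = "T" if seq[195] != "T" else "A"
    tip_read = seq[120:195] + flip
    reads = [seq[i:i + 80] for i in range(0, 221, 2)] * 2 + [tip_read, tip_read]
    g = build_graph(reads, 31, min_count=2)
    true_nodes = set(oracle_nodes([seq], 31))
    assert any(decode_kmer(c, 31) not in true_nodes for c in g.counts)
    prune(g, tip_max_len=62)
    got = {decode_kmer(c, 31) for c in g.counts}
    assert got <= true_nodes
    before = dict(g.counts)
    prune(g, tip_max_len=62)
    assert g.counts == before


def test_linear_graph_unchanged_by_pruning(rng):
    seq = "".join(rng.choice(list("ACGT"), 200))
    g = build_graph([seq], 31, min_count=1)
    n = len(g)
    prune(g)
    pop_bubbles(g)
    assert len(g) == n


def test_tiled_reads_reassemble_the_genome(rng):
    genome = "".join(rng.choice(list("ACGT"), 1000))
    reads = [genome[i:i + 100] for i in range(0, 901, 3)] * 3
    g = build_graph(reads, 31, min_count=2)
    contigs = extract_unitigs(g)
    assert len(contigs) == 1
    assert contigs[0] == min(genome, revcomp(genome))


def test_repeat_genome_matches_oracle_decomposition(rng):
    """Genome A-R-B-R-C with an exact 50-bp repeat fragments exactly like the
    brute-force decomposition of the genome's k-mer graph."""
    r = "".join(rng.choice(list("ACGT"), 50))
    a, b, c = ("".join(rng.choice(list("ACGT"), n)) for n in (400, 400, 400))
    genome = a + r + b + r + c
    reads = [genome[i:i + 90] for i in range(0, len(genome) - 89, 2)]
    g = build_graph(reads, 31, min_count=1)
    got = extract_unitigs(g)
    expect = oracle_unitigs(oracle_nodes([genome], 31), 31)
    assert got == expect
    assert len(got) >= 3


def test_strand_invariance(rng):
    genome = "".join(rng.choice(list("ACGT"), 600))
    reads = [genome[i:i + 80] for i in range(0, 521, 4)]
    fwd = extract_unitigs(build_graph(reads, 31, min_count=1))
    rev = extract_unitigs(build_graph([revcomp(x) for x in reads], 31, min_count=1))
    assert fwd == rev


def test_no_contig_kmer_outside_graph(rng):
    genome = "".join(rng.choice(list("ACGT"), 800))
    reads = [genome[i:i + 90] for i in range(0, 711, 3)]
    g = build_graph(reads, 31, min_count=1)
    node_set = set(g.counts)
    for contig in extract_unitigs(g):
        for code in kmer_codes(contig, 31).tolist():
            assert code in node_set


# ---------------------------------------------------------------------------
# scaffolding
# ---------------------------------------------------------------------------

def _spanning_pairs(genome, positions, insert, rlen=100):
    out = []
    for j, i in enumerate(positions):
        m1 = genome[i:i + rlen]
        m2 = revcomp(genome[i + insert - rlen:i + insert])
        out.append(ReadPair(f"sp{j}", m1, "F" * rlen, m2, "F" * rlen))
    return out


def test_spanning_pairs_join_two_contigs(rng):
    genome = "".join(rng.choice(list("ACGT"), 3000))
    contigs = [genome[:1400], genome[1600:]]
    pairs = _spanning_pairs(genome, [1295, 1300, 1305, 1310, 1315], 400)
    scaffolds = scaffold_contigs(contigs, pairs, 400, 30, min_links=3)
    assert len(scaffolds) == 1
    s = scaffolds[0]
    assert s.id == "scaffold_1"
    gapless = [p for p in s.sequence.split("N") if p]
    want = {min(c, revcomp(c)) for c in contigs}
    assert {min(p, revcomp(p)) for p in gapless} == want
    assert abs(s.length - 3000) <= 10  # estimated gap close to the true 200


def test_insufficient_links_leave_contigs_apart(rng):
    genome = "".join(rng.choice(list("ACGT"), 3000))
    contigs = [genome[:1400], genome[1600:]]
    pairs = _spanning_pairs(genome, [1300, 1310], 400)
    scaffolds = scaffold_contigs(contigs, pairs, 400, 30, min_links=3)
    assert len(scaffolds) == 2
    assert scaffolds[0].id == "scaffold_1"
    assert scaffolds[0].length >= scaffolds[1].length


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_published_scaffold_table_totals():
    stats = stats_from_rows(YERA41_SCAFFOLDS)
    table = stats.table()
    assert table[-1] == ("TOTAL/Average", 143_296, 32.3)
    assert stats.n_scaffolds == 9
    # cumulative 42,987+27,377 = 70,364 < 71,648 (half of total): N50 is row 3
    assert stats.n50 == 26_591


def test_single_scaffold_stats():
    s = Scaffold("scaffold_1", "ATGC")
    st = assembly_stats([s])
    assert (st.total_bp, st.n50) == (4, 4)
    assert st.weighted_gc == pytest.approx(50.0)


def test_empty_assembly_reports_zeros():
    st = assembly_stats([])
    assert (st.n_scaffolds, st.total_bp, st.n50) == (0, 0, 0)
    assert st.table() == [("TOTAL/Average", 0, 0.0)]


def test_gc_ignores_gap_ns():
    s = Scaffold("scaffold_1", "GGGNNNNCCC")
    assert s.gc == pytest.approx(1.0)
    assert s.length == 10
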