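"""Minimal de Bruijn assembler for the subtracted (non-host) read pool.

Nodes are canonical k-mers with counts; adjacency is implied by exact
(k-1)-mer overlap between retained nodes, which at k=31 on desk-scale data
coincides with read-adjacency. Cleaning removes low-coverage tips and, by
default, the weaker arm of simple bubbles (recurrent sequencing errors pass a
fixed count threshold once pooled coverage is high, so uncorrected bubbles
shatter unitigs). Contigs are maximal non-branching paths in canonical
orientation; paired reads then order and orient contigs into N-gapped
scaffolds, numbered by descending length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .kmers import kmer_codes, decode_kmer
from .seqs import ReadPair, revcomp, gc_content

log = logging.getLogger(__name__)


def _round1(x: float) -> float:
    """Round half-up to one decimal (display rule for GC percentages)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class DeBruijnGraph:
    """Canonical k-mer count graph with oriented traversal helpers.

    Oriented k-mers are handled as (forward-int, reverse-complement-int)
    pairs so reverse complements cost O(1) during walks.
    """

    def __init__(self, k: int, counts: dict[int, int]):
        self.k = k
        self.counts = counts
        self._mask = (1 << (2 * k)) - 1
        self._hi = 2 * (k - 1)

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, canon_code: int) -> bool:
        return canon_code in self.counts

    def successors(self, f: int, r: int) -> list[tuple[int, int]]:
        """Oriented successors of oriented k-mer (f, r)."""
        out = []
        for b in range(4):
            yf = ((f << 2) | b) & self._mask
            yr = (r >> 2) | ((3 - b) << self._hi)
            if min(yf, yr) in self.counts:
                out.append((yf, yr))
        return out

    def predecessors(self, f: int, r: int) -> list[tuple[int, int]]:
        out = []
        for b in range(4):
            zf = (b << self._hi) | (f >> 2)
            zr = ((r << 2) | (3 - b)) & self._mask
            if min(zf, zr) in self.counts:
                out.append((zf, zr))
        return out

    def n_edges(self) -> int:
        """Number of distinct undirected (k-1)-overlap adjacencies."""
        edges: set[frozenset[int]] = set()
        for canon in self.counts:
            f, r = canon, _rc_int(canon, self.k)
            for vf, vr in ((f, r), (r, f)):
                for yf, yr in self.successors(vf, vr):
                    edges.add(frozenset((canon, min(yf, yr))))
        return len(edges)


def _rc_int(code: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def build_graph(reads: Iterable[str], k: int = 31, min_count: int = 2) -> DeBruijnGraph:
    """Count canonical k-mers over all read sequences; keep count >= min_count."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    from .kmers import batch_kmer_codes
    reads = list(reads)
    if not reads:
        return DeBruijnGraph(k, {})
    flat, _ = batch_kmer_codes(reads, k)
    flat = flat[flat >= 0]
    if len(flat) == 0:
        return DeBruijnGraph(k, {})
    codes, counts = np.unique(flat, return_counts=True)
    keep = counts >= min_count
    return DeBruijnGraph(k, dict(zip(codes[keep].tolist(), counts[keep].tolist())))


# ---------------------------------------------------------------------------
# Unitigs
# ---------------------------------------------------------------------------

@dataclass
class Unitig:
    seq: str
    nodes: list[int]            # canonical codes along the path
    mean_cov: float
    left_ext: list[tuple[int, int]] = field(default_factory=list)   # oriented preds
    right_ext: list[tuple[int, int]] = field(default_factory=list)  # oriented succs


def _walk_unitigs(graph: DeBruijnGraph) -> list[Unitig]:
    """Maximal non-branching paths; every retained k-mer lands in exactly one."""
    k = graph.k
    visited: set[int] = set()
    unitigs: list[Unitig] = []
    for canon in sorted(graph.counts):
        if canon in visited:
            continue
        f, r = canon, _rc_int(canon, k)
        path = [(f, r)]
        seen = {canon}
        # extend right then left under the unique-extension rule
        for direction in (1, 0):
            while True:
                cf, cr = path[-1] if direction else path[0]
                if direction:
                    nxt = graph.successors(cf, cr)
                    if len(nxt) != 1:
                        break
                    yf, yr = nxt[0]
                    if len(graph.predecessors(yf, yr)) != 1:
                        break
                else:
                    nxt = graph.predecessors(cf, cr)
                    if len(nxt) != 1:
                        break
                    yf, yr = nxt[0]
                    if len(graph.successors(yf, yr)) != 1:
                        break
                ycanon = min(yf, yr)
                if ycanon in seen or ycanon in visited:
                    break  # cycle or collision with a finished unitig
                seen.add(ycanon)
                if direction:
                    path.append((yf, yr))
                else:
                    path.insert(0, (yf, yr))
        nodes = [min(f_, r_) for f_, r_ in path]
        visited.update(nodes)
        seq = decode_kmer(path[0][0], k) + "".join(
            "ACGT"[f_ & 3] for f_, _ in path[1:])
        cov = sum(graph.counts[c] for c in nodes) / len(nodes)
        lf, lr = path[0]
        rf, rr = path[-1]
        unitigs.append(Unitig(seq, nodes, cov,
                              left_ext=graph.predecessors(lf, lr),
                              right_ext=graph.successors(rf, rr)))
    return unitigs


def extract_unitigs(graph: DeBruijnGraph, min_len: int = 0) -> list[str]:
    """Contigs in canonical orientation (lexicographic min of seq/revcomp),
    sorted by descending length then sequence; optionally length-filtered."""
    seqs = []
    for u in _walk_unitigs(graph):
        rc = revcomp(u.seq)
        seqs.append(min(u.seq, rc))
    seqs = [s for s in seqs if len(s) >= min_len]
    seqs.sort(key=lambda s: (-len(s), s))
    return seqs


# ---------------------------------------------------------------------------
# Graph cleaning
# ---------------------------------------------------------------------------

def prune(graph: DeBruijnGraph, tip_max_len: int | None = None,
          max_rounds: int = 20) -> DeBruijnGraph:
    """Remove short dead-end paths (tips) with lower coverage than a sibling
    branch; iterates to fixpoint. Mutates and returns the graph."""
    if tip_max_len is None:
        tip_max_len = 2 * graph.k
    if tip_max_len < graph.k:
        raise ValueError("tip_max_len must be >= k")
    for _ in range(max_rounds):
        removed = _prune_once(graph, tip_max_len)
        if not removed:
            break
    return graph


def _junction_sibling_cov(graph: DeBruijnGraph, ext: list[tuple[int, int]],
                          own_nodes: set[int]) -> float:
    """Max count among nodes adjacent to the junction, excluding the tip itself."""
    best = 0.0
    for jf, jr in ext:
        for nf, nr in graph.successors(jf, jr) + graph.predecessors(jf, jr):
            c = min(nf, nr)
            if c not in own_nodes:
                best = max(best, graph.counts.get(c, 0))
    return best


def _prune_once(graph: DeBruijnGraph, tip_max_len: int) -> int:
    removed = 0
    for u in _walk_unitigs(graph):
        dead_left = not u.left_ext
        dead_right = not u.right_ext
        if dead_left == dead_right:
            continue  # interior unitig or isolated island: not a tip
        if len(u.seq) >= tip_max_len:
            continue
        ext = u.right_ext if dead_left else u.left_ext
        own = set(u.nodes)
        if u.mean_cov < _junction_sibling_cov(graph, ext, own):
            for c in u.nodes:
                graph.counts.pop(c, None)
            removed += 1
    return removed


def pop_bubbles(graph: DeBruijnGraph, ratio: float = 0.25,
                max_len: int | None = None, max_rounds: int = 20) -> DeBruijnGraph:
    """Remove the weaker arm of simple bubbles.

    Two unitigs form a simple bubble when they run between the same pair of
    junction k-mers; the arm whose mean coverage is <= ratio x the stronger
    arm's is deleted. Needed because recurrent errors exceed min_count once
    pooled coverage is high.
    """
    if max_len is None:
        max_len = 5 * graph.k
    for _ in range(max_rounds):
        removed = 0
        groups: dict[tuple[int, int], list[Unitig]] = {}
        for u in _walk_unitigs(graph):
            if len(u.left_ext) != 1 or len(u.right_ext) != 1:
                continue
            a = min(u.left_ext[0])
            b = min(u.right_ext[0])
            groups.setdefault((min(a, b), max(a, b)), []).append(u)
        for arms in groups.values():
            if len(arms) < 2:
                continue
            arms.sort(key=lambda u: (-u.mean_cov, u.seq))
            best = arms[0]
            for u in arms[1:]:
                if len(u.seq) <= max_len and u.mean_cov <= ratio * best.mean_cov:
                    for c in u.nodes:
                        graph.counts.pop(c, None)
                    removed += 1
        if not removed:
            break
    return graph


def clean_graph(graph: DeBruijnGraph, tip_max_len: int | None = None,
                ratio: float = 0.25, max_len: int | None = None,
                max_rounds: int = 8) -> DeBruijnGraph:
    """One-pass-per-round combined cleaning: tips and short low-coverage
    unitigs (bubble arms, error tangles) removed together, iterated to
    fixpoint or max_rounds. Equivalent to interleaving :func:`prune` and
    :func:`clean_low_coverage` but walks the graph once per round."""
    if tip_max_len is None:
        tip_max_len = 2 * graph.k
    if max_len is None:
        max_len = 5 * graph.k
    for _ in range(max_rounds):
        unis = _walk_unitigs(graph)
        node2uni: dict[int, int] = {}
        for i, u in enumerate(unis):
            for c in u.nodes:
                node2uni[c] = i
        removed = 0
        for i, u in enumerate(unis):
            dead_left = not u.left_ext
            dead_right = not u.right_ext
            kill = False
            if dead_left != dead_right and len(u.seq) < tip_max_len:
                ext = u.right_ext if dead_left else u.left_ext
                if u.mean_cov < _junction_sibling_cov(graph, ext, set(u.nodes)):
                    kill = True
            if not kill and len(u.seq) <= max_len:
                nb = {node2uni[min(f, r)] for f, r in u.left_ext + u.right_ext}
                nb.discard(i)
                nbcov = max((unis[j].mean_cov for j in nb), default=0.0)
                if nbcov > 0 and u.mean_cov <= ratio * nbcov:
                    kill = True
            if kill:
                for c in u.nodes:
                    graph.counts.pop(c, None)
                removed += 1
        if not removed:
            break
    return graph


def clean_low_coverage(graph: DeBruijnGraph, ratio: float = 0.2,
                       max_len: int | None = None,
                       max_rounds: int = 30) -> DeBruijnGraph:
    """Remove short unitigs whose coverage is a small fraction of their
    strongest neighbour's.

    Generalizes tip and bubble removal: at high pooled coverage, recurrent
    sequencing errors pass a fixed count threshold and branch off the true
    path in tangles that are neither clean tips nor simple two-arm bubbles.
    A short unitig with mean coverage <= ratio x the best adjacent unitig is
    error-derived under that regime and is deleted; true low-coverage regions
    are safe because coverage varies continuously along the genome. Iterates
    to fixpoint.
    """
    if max_len is None:
        max_len = 5 * graph.k
    for _ in range(max_rounds):
        unis = _walk_unitigs(graph)
        node2uni: dict[int, int] = {}
        for i, u in enumerate(unis):
            for c in u.nodes:
                node2uni[c] = i
        removed = 0
        for i, u in enumerate(unis):
            if len(u.seq) > max_len:
                continue
            nb = {node2uni[min(f, r)] for f, r in u.left_ext + u.right_ext}
            nb.discard(i)
            nbcov = max((unis[j].mean_cov for j in nb), default=0.0)
            if nbcov > 0 and u.mean_cov <= ratio * nbcov:
                for c in u.nodes:
                    graph.counts.pop(c, None)
                removed += 1
        if not removed:
            break
    return graph


# ---------------------------------------------------------------------------
# Scaffolding
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    id: str
    sequence: str
    members: list[tuple[str, int, str]] = field(default_factory=list)  # (contig id, offset, orient)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence.replace("N", ""))


def _anchor_map(contigs: Sequence[str], k: int) -> dict[int, tuple[int, int, int]]:
    """canonical k-mer -> (contig idx, position, fwd int); multi-hit k-mers dropped."""
    anchors: dict[int, tuple[int, int, int]] = {}
    dup: set[int] = set()
    for ci, seq in enumerate(contigs):
        fwd = kmer_codes(seq, k, canonical=False)
        canon = kmer_codes(seq, k, canonical=True)
        for pos, (cf, cc) in enumerate(zip(fwd.tolist(), canon.tolist())):
            if cc in dup:
                continue
            if cc in anchors:
                del anchors[cc]
                dup.add(cc)
            else:
                anchors[cc] = (ci, pos, cf)
    return anchors


def _anchor_read(seq: str, k: int, anchors: dict[int, tuple[int, int, int]],
                 min_hits: int) -> tuple[int, int, int] | None:
    """Place one mate: returns (contig idx, strand +1/-1, leftmost ref pos)."""
    fwd = kmer_codes(seq, k, canonical=False)
    canon = kmer_codes(seq, k, canonical=True)
    votes: dict[tuple[int, int], list[int]] = {}
    for i, (rf, rc_) in enumerate(zip(fwd.tolist(), canon.tolist())):
        hit = anchors.get(rc_)
        if hit is None:
            continue
        ci, pos, cf = hit
        if rf == cf:
            votes.setdefault((ci, 1), []).append(pos - i)
        else:
            votes.setdefault((ci, -1), []).append(pos - (len(seq) - k - i))
    if not votes:
        return None
    key = max(votes, key=lambda kk: (len(votes[kk]), kk))
    if len(votes[key]) < min_hits:
        return None
    ci, strand = key
    return ci, strand, int(median(votes[key]))


def scaffold_contigs(contigs: Sequence[str], pairs: Iterable[ReadPair],
                     insert_mean: float, insert_sd: float,
                     min_links: int = 3, k: int = 31,
                     anchor_min_hits: int = 5) -> list[Scaffold]:
    """Join contigs supported by >= min_links uniquely anchored read pairs.

    A mate anchored on strand + points out of the contig's right end, strand -
    out of the left end; an FR pair therefore links one end of each contig.
    For each contig pair the best end-combination must strictly beat the
    runner-up (equal support = contradictory evidence, no join). Chains become
    scaffolds with gap = max(1, round(insert_mean - overhangs)) Ns, renumbered
    by descending length.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    contigs = list(contigs)
    anchors = _anchor_map(contigs, k)
    # collect link evidence between contig ends
    links: dict[tuple[tuple[int, str], tuple[int, str]], list[float]] = {}
    for p in pairs:
        a1 = _anchor_read(p.seq1, k, anchors, anchor_min_hits)
        a2 = _anchor_read(p.seq2, k, anchors, anchor_min_hits)
        if a1 is None or a2 is None or a1[0] == a2[0]:
            continue
        ends, overhangs = [], []
        for (ci, strand, pos), rlen in ((a1, len(p.seq1)), (a2, len(p.seq2))):
            if strand > 0:
                ends.append((ci, "R"))
                overhangs.append(len(contigs[ci]) - pos)
            else:
                ends.append((ci, "L"))
                overhangs.append(pos + rlen)
        gap = insert_mean - sum(overhangs)
        key = tuple(sorted(ends))
        links.setdefault(key, []).append(gap)

    # per contig pair: require the dominant end-combination to be unambiguous
    by_pair: dict[tuple[int, int], list[tuple[int, tuple]]] = {}
    for key, gaps in links.items():
        if len(gaps) < min_links:
            continue
        cpair = tuple(sorted((key[0][0], key[1][0])))
        by_pair.setdefault(cpair, []).append((len(gaps), key))
    edges = []
    for cpair, cands in by_pair.items():
        cands.sort(key=lambda t: (-t[0], t[1]))
        if len(cands) > 1 and cands[0][0] == cands[1][0]:
            log.warning("contigs %s: contradictory link orientations with equal "
                        "support; left unjoined", cpair)
            continue
        support, key = cands[0]
        edges.append((support, key, links[key]))
    edges.sort(key=lambda t: (-t[0], t[1]))

    # greedy chaining: each contig end used at most once, no cycles
    end_used: set[tuple[int, str]] = set()
    parent = list(range(len(contigs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted = []
    for support, key, gaps in edges:
        (c1, e1), (c2, e2) = key
        if (c1, e1) in end_used or (c2, e2) in end_used:
            continue
        if find(c1) == find(c2):
            continue
        end_used.add((c1, e1))
        end_used.add((c2, e2))
        parent[find(c1)] = find(c2)
        gap = max(1, round(median(gaps)))
        accepted.append(((c1, e1), (c2, e2), gap))

    # build chains
    adj: dict[tuple[int, str], tuple[tuple[int, str], int]] = {}
    for (a, b, gap) in accepted:
        adj[a] = (b, gap)
        adj[b] = (a, gap)
    scaffolds: list[Scaffold] = []
    placed: set[int] = set()
    order = sorted(range(len(contigs)), key=lambda i: (-len(contigs[i]), contigs[i]))
    for start in order:
        if start in placed:
            continue
        # walk out of the left end repeatedly to find a chain endpoint
        cur, out = start, "L"
        seen = {start}
        while True:
            nxt = adj.get((cur, out))
            if nxt is None:
                break
            (nc, nend), _ = nxt
            if nc in seen:
                break  # circular chain: break arbitrarily at `start`
            seen.add(nc)
            cur, out = nc, ("R" if nend == "L" else "L")
        # `cur`'s free end `out` starts the chain; orient it to face left
        seq_parts: list[str] = []
        members: list[tuple[str, int, str]] = []
        entry = out
        offset = 0
        while True:
            placed.add(cur)
            orient = "+" if entry == "L" else "-"
            cseq = contigs[cur] if orient == "+" else revcomp(contigs[cur])
            seq_parts.append(cseq)
            members.append((f"contig_{cur + 1}", offset, orient))
            offset += len(cseq)
            out_end = "R" if entry == "L" else "L"
            nxt = adj.get((cur, out_end))
            if nxt is None:
                break
            (ncur, nend), gap = nxt
            if ncur in placed:
                break
            seq_parts.append("N" * gap)
            offset += gap
            cur, entry = ncur, nend
        scaffolds.append(Scaffold("tmp", "".join(seq_parts), members))

    scaffolds.sort(key=lambda s: (-s.length, s.sequence))
    for i, s in enumerate(scaffolds, 1):
        s.id = f"scaffold_{i}"
    return scaffolds


# ---------------------------------------------------------------------------
# Assembly statistics (Table-2-style summary)
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    weighted_gc: float  # percent
    n50: int
    rows: list[tuple[str, int, float]]  # (id, length, gc percent)

    def table(self) -> list[tuple[str, object, object]]:
        """Per-scaffold rows plus a TOTAL/Average line, GC% half-up 1 decimal."""
        out: list[tuple[str, object, object]] = [
            (sid, length, _round1(gc)) for sid, length, gc in self.rows]
        out.append(("TOTAL/Average", self.total_bp, _round1(self.weighted_gc)))
        return out


def _n50(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 2 >= total:
            return length
    return 0


def stats_from_rows(rows: Sequence[tuple[str, int, float]]) -> AssemblyStats:
    """Summary from (id, length, GC percent) rows, e.g. a published scaffold table."""
    if not rows:
        return AssemblyStats(0, 0, 0.0, 0, [])
    lengths = [r[1] for r in rows]
    total = sum(lengths)
    wgc = sum(r[1] * r[2] for r in rows) / total
    return AssemblyStats(len(rows), total, wgc, _n50(lengths), list(rows))


def assembly_stats(scaffolds: Sequence[Scaffold]) -> AssemblyStats:
    """Count, total bp, length-weighted GC% (per-scaffold GC over non-N bases),
    and N50. Empty input gives an empty report, not an exception."""
    rows = [(s.id, s.length, 100.0 * s.gc) for s in scaffolds]
    return stats_from_rows(rows)
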