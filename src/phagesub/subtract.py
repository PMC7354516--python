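"""Host-read subtraction.

The reference study aligned reads to the host chromosome and plasmids and
assembled what failed to align. Here alignment is replaced by a canonical
k-mer membership surrogate: a mate is host-like when the fraction of its
k-mers found in the host index reaches a threshold, and a pair is routed to
the host pool when either mate is host-like (conservative against host
contamination of the assembly pool). Reads shorter than k are never host-like
and are flagged, not lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .kmers import KmerIndex
from .seqs import ReadPair


def host_kmer_fraction(read: str, index: KmerIndex) -> float:
    """Fraction of the read's k-mers present in the host index.

    Denominator is len(read)-k+1; reads shorter than k return 0.0.
    """
    return index.fraction_in(read)


@dataclass
class SubtractReport:
    pairs_in: int = 0
    pairs_host: int = 0
    pairs_nonhost: int = 0
    pairs_short: int = 0  # at least one mate shorter than k (routed nonhost)
    threshold: float = 0.5
    k: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("pairs_in", "pairs_host", "pairs_nonhost", "pairs_short",
                 "threshold", "k")}


def subtract_pairs(pairs: Iterable[ReadPair], index: KmerIndex,
                   threshold: float = 0.5,
                   ) -> tuple[list[ReadPair], list[ReadPair], SubtractReport]:
    """Partition pairs into (host pool, nonhost pool, report).

    A pair is host iff either mate's host k-mer fraction >= threshold.
    The two pools always partition the input.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    import numpy as np
    from .kmers import batch_kmer_codes
    pairs = list(pairs)
    report = SubtractReport(threshold=threshold, k=index.k)
    report.pairs_in = len(pairs)
    host: list[ReadPair] = []
    nonhost: list[ReadPair] = []
    if not pairs:
        return host, nonhost, report
    k = index.k
    seqs = [s for p in pairs for s in (p.seq1, p.seq2)]
    codes, offsets = batch_kmer_codes(seqs, k)
    hits = index.contains_codes(codes).astype(np.int64)
    if len(hits):
        starts = np.minimum(offsets[:-1], len(hits) - 1)
        per_read = np.add.reduceat(hits, starts)
        per_read[offsets[:-1] == offsets[1:]] = 0  # reads shorter than k
    else:
        per_read = np.zeros(len(seqs), dtype=np.int64)
    windows = np.maximum(np.fromiter((len(s) for s in seqs), dtype=np.int64,
                                     count=len(seqs)) - k + 1, 1)
    frac = per_read / windows
    for i, p in enumerate(pairs):
        if len(p.seq1) < k or len(p.seq2) < k:
            report.pairs_short += 1
        if max(frac[2 * i], frac[2 * i + 1]) >= threshold:
            host.append(p)
            report.pairs_host += 1
        else:
            nonhost.append(p)
            report.pairs_nonhost += 1
    return host, nonhost, report
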