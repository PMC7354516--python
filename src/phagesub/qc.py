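"""Read quality filtering — the first pipeline stage.

Sliding-window 3' quality trimming in the style of Trimmomatic's
SLIDINGWINDOW: the read is cut at the start of the first window whose mean
Phred score falls below the threshold, then consecutive bases that
individually meet the threshold are kept. A pair survives only if both mates
survive the minimum-length check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .seqs import ReadPair

PHRED_OFFSET = 33


def phred(qual: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in qual]


def trim_read(seq: str, qual: str, window: int = 4, min_q: int = 20,
              min_len: int = 50) -> tuple[str, str] | None:
    """Trim a read 3' by sliding-window mean quality.

    Returns the trimmed (seq, qual) or None if the survivor is shorter than
    ``min_len``. Raises ValueError on a sequence/quality length mismatch.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    q = phred(qual)
    n = len(q)
    # fast path: every base passes => no window can fail
    if n == 0 or min(q) >= min_q:
        return (seq, qual) if n >= min_len else None
    cut = n
    thresh = min_q * window
    if n >= window:
        s = sum(q[:window])
        for i in range(n - window + 1):
            if i:
                s += q[i + window - 1] - q[i - 1]
            if s < thresh:
                cut = i
                break
    # keep trailing bases of the failing window that individually pass
    while cut < n and q[cut] >= min_q:
        cut += 1
    if cut < min_len:
        return None
    return seq[:cut], qual[:cut]


@dataclass
class QcReport:
    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_dropped: int = 0
    bases_in: int = 0
    bases_kept: int = 0
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "pairs_kept": self.pairs_kept,
            "pairs_dropped": self.pairs_dropped,
            "bases_in": self.bases_in,
            "bases_kept": self.bases_kept,
        }


def filter_pairs(pairs: Iterable[ReadPair], window: int = 4, min_q: int = 20,
                 min_len: int = 50,
                 report: QcReport | None = None) -> Iterator[ReadPair]:
    """Yield pairs in which both mates survive trimming; tallies into report."""
    if report is None:
        report = QcReport()
    report.params = {"window": window, "min_q": min_q, "min_len": min_len}
    for p in pairs:
        report.pairs_in += 1
        report.bases_in += len(p.seq1) + len(p.seq2)
        try:
            t1 = trim_read(p.seq1, p.qual1, window, min_q, min_len)
            t2 = trim_read(p.seq2, p.qual2, window, min_q, min_len)
        except ValueError as exc:
            raise ValueError(f"record {p.id!r}: {exc}") from exc
        if t1 is None or t2 is None:
            report.pairs_dropped += 1
            continue
        report.pairs_kept += 1
        report.bases_kept += len(t1[0]) + len(t2[0])
        yield ReadPair(p.id, t1[0], t1[1], t2[0], t2[1])
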