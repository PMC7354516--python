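"""Canonical k-mer indexing.

A canonical k-mer is the lexicographically smaller of a k-mer and its reverse
complement, which makes k-mer sets strand-invariant. K-mers are packed into
64-bit integers (2 bits/base, A=0 C=1 G=2 T=3; the integer order equals the
lexicographic order of the strings), so k <= 31. Windows containing N are
skipped.

One index class serves three pipeline stages: host-read subtraction,
scaffold decontamination, and per-gene read counting.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes; 255 marks N/invalid characters."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """All k-mer codes of ``seq`` in order; N-containing windows are dropped.

    Returns an int64 array of length <= len(seq)-k+1 (empty if the sequence is
    shorter than k).
    """
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    codes = encode_bases(seq)
    valid = codes != 255
    codes = np.where(valid, codes, 0).astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pw
    # windows containing any N are invalid
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    if canonical:
        rcwin = 3 - win[:, ::-1]
        rev = rcwin @ pw
        fwd = np.minimum(fwd, rev)
    return fwd[ok]


def batch_kmer_codes(seqs: list[str], k: int,
                     row_chunk: int = 20_000) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for many sequences in one vectorized pass.

    Returns (codes, offsets): sequence i owns codes[offsets[i]:offsets[i+1]],
    one slot per window (len(seq)-k+1; zero for sequences shorter than k).
    N-containing windows hold the sentinel -1, which matches nothing.
    """
    n = len(seqs)
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    nwin = np.maximum(lens - k + 1, 0)
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(nwin, out=offsets[1:])
    out = np.empty(int(offsets[-1]), dtype=np.int64)
    bylen: dict[int, list[int]] = {}
    for i, L in enumerate(lens.tolist()):
        if L >= k:
            bylen.setdefault(L, []).append(i)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for L, idxs in bylen.items():
        for c0 in range(0, len(idxs), row_chunk):
            chunk = idxs[c0:c0 + row_chunk]
            arr = _CODE[np.frombuffer(
                "".join(seqs[i] for i in chunk).encode("ascii"),
                dtype=np.uint8)].reshape(len(chunk), L)
            valid = arr != 255
            a = np.where(valid, arr, 0).astype(np.int64)
            W = L - k + 1
            m = len(chunk)
            mask = (1 << (2 * k)) - 1
            hi = 2 * (k - 1)
            fwd = np.empty((m, W), dtype=np.int64)
            rev = np.empty((m, W), dtype=np.int64)
            fwd[:, 0] = a[:, :k] @ pw
            rev[:, 0] = (3 - a[:, :k]) @ pw[::-1]
            for j in range(1, W):
                fwd[:, j] = ((fwd[:, j - 1] << 2) & mask) | a[:, k + j - 1]
                rev[:, j] = (rev[:, j - 1] >> 2) | ((3 - a[:, k + j - 1]) << hi)
            codes = np.minimum(fwd, rev)
            # windows containing any N are invalidated
            bad = ~valid
            if bad.any():
                cum = np.zeros((m, L + 1), dtype=np.int64)
                np.cumsum(bad, axis=1, out=cum[:, 1:])
                codes[(cum[:, k:] - cum[:, :W]) > 0] = -1
            if len(bylen) == 1 and len(idxs) == n and n <= row_chunk:
                return codes.ravel(), offsets
            for row, i in enumerate(chunk):
                out[offsets[i]:offsets[i + 1]] = codes[row]
    return out, offsets


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


class KmerIndex:
    """Set of canonical k-mers over one or more reference sequences."""

    def __init__(self, k: int, codes: np.ndarray | None = None,
                 source_ids: list[str] | None = None):
        if k % 2 == 0:
            raise ValueError(f"k must be odd (got {k}): an odd k guarantees no "
                             "k-mer is its own reverse complement")
        self.k = k
        self._sorted = np.unique(codes) if codes is not None and len(codes) else \
            np.empty(0, dtype=np.int64)
        self.source_ids = source_ids or []

    def __len__(self) -> int:
        return len(self._sorted)

    def __contains__(self, kmer: str) -> bool:
        codes = kmer_codes(kmer, self.k)
        if len(codes) != 1:
            return False
        return bool(self.contains_codes(codes)[0])

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of canonical k-mer codes."""
        if len(self._sorted) == 0:
            return np.zeros(len(codes), dtype=bool)
        pos = np.searchsorted(self._sorted, codes)
        pos = np.clip(pos, 0, len(self._sorted) - 1)
        return self._sorted[pos] == codes

    def fraction_in(self, seq: str, valid_denominator: bool = False) -> float:
        """Fraction of the sequence's k-mers present in the index.

        With ``valid_denominator=False`` (read classification) the denominator
        is every window, len(seq)-k+1, so N-containing windows count as
        misses; with True (scaffold identity screening) only N-free windows
        are counted. Sequences shorter than k yield 0.0.
        """
        if len(seq) < self.k:
            return 0.0
        codes = kmer_codes(seq, self.k)
        if len(codes) == 0:
            return 0.0
        hits = int(self.contains_codes(codes).sum())
        denom = len(codes) if valid_denominator else len(seq) - self.k + 1
        return hits / denom


def build_index(references: Iterable[str], k: int,
                source_ids: list[str] | None = None,
                k_min: int = 15, k_max: int = 31) -> KmerIndex:
    """Canonical k-mer index over all reference sequences (both strands implied).

    k must be odd and within [k_min, k_max]; references shorter than k
    contribute nothing.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not (k_min <= k <= k_max):
        raise ValueError(f"k={k} outside supported range [{k_min}, {k_max}]")
    parts = [kmer_codes(ref, k) for ref in references]
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    return KmerIndex(k, codes, source_ids)
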