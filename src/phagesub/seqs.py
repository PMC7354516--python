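"""Sequence utilities and light-weight file I/O shared across the pipeline.

FASTA parsing/writing goes through Biopython; FASTQ uses Biopython's fast
``FastqGeneralIterator``. GFF3 is round-tripped with a minimal reader/writer
(gene-level features only, 1-based inclusive coordinates).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: substitution table used when injecting sequencing errors / mutating bases
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases; 0.0 for empty/all-N input."""
    acgt = sum(seq.count(b) for b in "ACGT") + sum(seq.count(b) for b in "acgt")
    if acgt == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    return gc / acgt


def random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random DNA with iid bases at the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class ReadPair:
    """A paired-end read with Phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"read {self.id!r}: sequence/quality length mismatch"
            )


def read_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike) -> Iterator[ReadPair]:
    """Iterate read pairs from two parallel FASTQ files."""
    with open(path1) as h1, open(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield ReadPair(t1.split()[0].removesuffix("/1"), s1, q1, s2, q2)


def write_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike,
                      pairs: Iterable[ReadPair]) -> int:
    """Write pairs to two FASTQ files; returns the number of pairs written."""
    n = 0
    buf1, buf2 = io.StringIO(), io.StringIO()
    for p in pairs:
        buf1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
        buf2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
        n += 1
    with open(path1, "w") as h:
        h.write(buf1.getvalue())
    with open(path2, "w") as h:
        h.write(buf2.getvalue())
    return n


# ---------------------------------------------------------------------------
# GFF3 (gene features, 1-based inclusive)
# ---------------------------------------------------------------------------

@dataclass
class GffFeature:
    seqid: str
    type: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    attributes: dict[str, str]


def read_gff3(path: str | os.PathLike, types: Sequence[str] = ("gene",)) -> list[GffFeature]:
    feats = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            if types and cols[2] not in types:
                continue
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            feats.append(GffFeature(cols[0], cols[2], int(cols[3]), int(cols[4]),
                                    cols[6], attrs))
    return feats


def write_gff3(path: str | os.PathLike, feats: Iterable[GffFeature],
               source: str = "phagesub") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in feats:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            handle.write(
                f"{f.seqid}\t{source}\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
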