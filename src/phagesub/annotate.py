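"""Gene prediction on phage scaffolds: six-frame ORF calling with
Shine-Dalgarno (ribosome-binding-site) verification.

For every stop codon in every frame the maximal open reading frame is
reported: it begins at the furthest upstream in-frame start codon with no
intervening stop, and includes the stop codon. Each candidate is scored for
an RBS — the longest contiguous substring of the AGGAGGT consensus found in
the -20..-4 window upstream of the start on the coding strand — and flagged
high-confidence when that score reaches 4. Start codons ATG/GTG/TTG and
translation table 11 are the bacterial/phage standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .seqs import GffFeature, revcomp

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
RBS_MOTIF = "AGGAGGT"
RBS_WINDOW = (-20, -4)  # relative to the first base of the start codon


@dataclass
class GeneModel:
    """Predicted gene; 1-based inclusive coordinates, start < end always,
    the strand carries direction; length divisible by 3 including the stop."""

    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    rbs_score: int = 0
    rbs_spacer: int = -1
    confidence: str = "low"

    def extract(self, seq: str) -> str:
        """Coding sequence on its own strand (starts with a start codon)."""
        sub = seq[self.start - 1:self.end]
        return sub if self.strand == "+" else revcomp(sub)

    def protein(self, seq: str) -> str:
        return str(Seq(self.extract(seq)).translate(table=11, to_stop=True))


def _orfs_one_strand(seq: str, min_codons: int,
                     starts: Sequence[str], stops: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal ORFs on the forward strand of ``seq`` as 0-based [s, e) spans."""
    out = []
    n = len(seq)
    starts = set(starts)
    stops = set(stops)
    for frame in range(3):
        first_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon in stops:
                if first_start is not None:
                    length = i + 3 - first_start
                    if length >= 3 * min_codons:
                        out.append((first_start, i + 3))
                first_start = None
            elif first_start is None and codon in starts:
                first_start = i
    return out


def find_orfs(seq: str, min_codons: int = 30,
              starts: Sequence[str] = START_CODONS,
              stops: Sequence[str] = STOP_CODONS) -> list[tuple[int, int, str]]:
    """Six-frame maximal ORFs as (start, end, strand), 1-based inclusive,
    stop codon included; min_codons counts codons including the stop."""
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    seq = seq.upper()
    n = len(seq)
    cands = [(s + 1, e, "+") for s, e in _orfs_one_strand(seq, min_codons, starts, stops)]
    for s, e in _orfs_one_strand(revcomp(seq), min_codons, starts, stops):
        cands.append((n - e + 1, n - s, "-"))
    cands.sort()
    return cands


def score_rbs(seq: str, start: int, end: int, strand: str,
              motif: str = RBS_MOTIF,
              window: tuple[int, int] = RBS_WINDOW) -> tuple[int, int]:
    """(score, spacer): score is the longest contiguous substring of the motif
    found in the upstream window on the coding strand; spacer is the distance
    from the match end to the start codon (max score, then minimal spacer).
    Window is truncated at the scaffold edge; score 0 reports spacer -1.
    """
    lo, hi = window
    if strand == "+":
        a = max(0, start - 1 + lo)
        b = max(0, start - 1 + hi + 1)
        up = seq[a:b]
        dist_to_start = (start - 1) - b  # bases between window end and start codon
    else:
        a = min(len(seq), end + (-hi - 1))
        b = min(len(seq), end - lo)
        up = revcomp(seq[a:b])
        dist_to_start = a - end  # on the coding strand
    best = (0, -1)
    for ln in range(min(len(motif), len(up)), 0, -1):
        if best[0] >= ln:
            break
        for ms in range(len(motif) - ln + 1):
            sub = motif[ms:ms + ln]
            pos = up.find(sub)
            while pos != -1:
                spacer = (len(up) - (pos + ln)) + dist_to_start
                if ln > best[0] or (ln == best[0] and spacer < best[1]):
                    best = (ln, spacer)
                pos = up.find(sub, pos + 1)
    return best


def call_genes(scaffolds: dict[str, str] | Iterable[tuple[str, str]],
               min_codons: int = 30,
               starts: Sequence[str] = START_CODONS,
               stops: Sequence[str] = STOP_CODONS,
               rbs_high: int = 4) -> list[GeneModel]:
    """Predict genes over all scaffolds.

    Same-stop overlapping ORFs are already resolved to the longest by the
    maximal-ORF rule; ids gNNN run in scaffold order then genomic position;
    confidence is high iff rbs_score >= rbs_high.
    """
    items = scaffolds.items() if isinstance(scaffolds, dict) else scaffolds
    genes: list[GeneModel] = []
    for sid, seq in items:
        for start, end, strand in find_orfs(seq, min_codons, starts, stops):
            score, spacer = score_rbs(seq, start, end, strand)
            genes.append(GeneModel(
                id="", scaffold=sid, start=start, end=end, strand=strand,
                rbs_score=score, rbs_spacer=spacer,
                confidence="high" if score >= rbs_high else "low"))
    width = max(3, len(str(len(genes))))
    for i, g in enumerate(genes, 1):
        g.id = f"g{i:0{width}d}"
    return genes


def genes_to_gff(genes: Sequence[GeneModel]) -> list[GffFeature]:
    feats = []
    for g in genes:
        attrs = {"ID": g.id, "rbs_score": str(g.rbs_score),
                 "rbs_spacer": str(g.rbs_spacer), "confidence": g.confidence,
                 "product": "hypothetical protein"}
        feats.append(GffFeature(g.scaffold, "gene", g.start, g.end, g.strand, attrs))
    return feats
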