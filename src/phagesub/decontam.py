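"""Host-identity screening of assembled scaffolds.

The study excluded contigs with high sequence identity to the host genus by
database BLAST; here scaffolds are screened against the supplied host
reference(s) only: identity = fraction of the scaffold's N-free canonical
k-mers found in the host index. Scaffolds below the identity ceiling and at
or above the length floor are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .assemble import Scaffold
from .kmers import KmerIndex


def host_identity(scaffold: Scaffold | str, host_index: KmerIndex) -> float:
    """Fraction of the scaffold's N-free canonical k-mers present in the host."""
    seq = scaffold.sequence if isinstance(scaffold, Scaffold) else scaffold
    return host_index.fraction_in(seq, valid_denominator=True)


@dataclass
class ScaffoldFate:
    id: str
    length: int
    identity: float
    kept: bool
    reason: str


def filter_scaffolds(scaffolds: Sequence[Scaffold], host_index: KmerIndex,
                     identity_max: float = 0.9, min_len: int = 1000,
                     ) -> tuple[list[Scaffold], list[Scaffold], list[ScaffoldFate]]:
    """Partition scaffolds into (kept, excluded) with a per-scaffold report.

    Kept iff host identity < identity_max and length >= min_len.
    """
    if not (0.0 <= identity_max <= 1.0):
        raise ValueError("identity_max must be in [0, 1]")
    kept, excluded, report = [], [], []
    for s in scaffolds:
        ident = host_identity(s, host_index)
        if ident >= identity_max:
            ok, reason = False, "host_identity"
        elif s.length < min_len:
            ok, reason = False, "too_short"
        else:
            ok, reason = True, "kept"
        (kept if ok else excluded).append(s)
        report.append(ScaffoldFate(s.id, s.length, ident, ok, reason))
    return kept, excluded, report
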