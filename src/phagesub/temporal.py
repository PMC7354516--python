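"""Temporal classification of phage genes.

Counts are CPM-normalized, replicates at the same timepoint averaged, and each
gene is assigned to the post-infection window — early (5-15 min), middle
(33-45 min), late (63-92 min) — whose mean expression is highest. Genes whose
expression never reaches min_cpm at any timepoint are flagged as artifacts
(the precedent being predicted genes with minimal, flat expression). For
heatmap display each gene is scaled to its own maximum, so color shows the
timing, not the level, of expression.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .quant import CountMatrix

#: default class windows, minutes post infection
WINDOWS: dict[str, tuple[float, ...]] = {
    "early": (5.0, 15.0),
    "middle": (33.0, 45.0),
    "late": (63.0, 75.0, 92.0),
}
CLASS_ORDER = ("early", "middle", "late")


def cpm_normalize(cm: CountMatrix, average_replicates: bool = True) -> pd.DataFrame:
    """Counts per million library pairs; replicate columns at the same
    timepoint are averaged, giving genes x timepoints (columns = minutes)."""
    lib = cm.meta["library_size"]
    if (lib <= 0).any():
        bad = lib[lib <= 0].index.tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = cm.counts.div(lib, axis=1) * 1e6
    if not average_replicates:
        return cpm
    tp = cm.meta["timepoint_min"]
    return cpm.T.groupby(tp).mean().T


def rowmax_normalize(cpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Each gene scaled to its own maximum (heatmap matrix). All-zero genes
    are left at zero and flagged in the returned boolean series."""
    mx = cpm.max(axis=1)
    zero = mx == 0
    scaled = cpm.div(mx.where(~zero, 1.0), axis=0)
    return scaled, zero


def window_means(cpm: pd.DataFrame,
                 windows: dict[str, tuple[float, ...]] = WINDOWS) -> pd.DataFrame:
    """Mean CPM per class window; every window must have >= 1 observed timepoint."""
    cols = {}
    have = set(float(c) for c in cpm.columns)
    for name, tps in windows.items():
        present = [t for t in tps if float(t) in have]
        if not present:
            raise ValueError(f"no timepoints observed for window {name!r}: {tps}")
        cols[name] = cpm[[c for c in cpm.columns if float(c) in set(map(float, present))]].mean(axis=1)
    return pd.DataFrame(cols)


def classify(cpm: pd.DataFrame, windows: dict[str, tuple[float, ...]] = WINDOWS,
             min_cpm: float = 1.0) -> pd.DataFrame:
    """Per-gene window means, class, and artifact flag.

    Class = argmax window mean; deterministic ties go to the earlier window.
    A gene is an artifact when its CPM is below min_cpm at every timepoint.
    """
    wm = window_means(cpm, windows)
    order = [w for w in CLASS_ORDER if w in wm.columns] + \
            [w for w in wm.columns if w not in CLASS_ORDER]
    cls = []
    for g in wm.index:
        vals = wm.loc[g, order]
        best = max(order, key=lambda w: (vals[w], -order.index(w)))
        cls.append(best)
    out = wm.copy()
    out["class"] = cls
    artifact = cpm.max(axis=1) < min_cpm
    out.loc[artifact, "class"] = "artifact"
    return out


def _pct1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def class_summary(classes: pd.Series | dict[str, int],
                  include: tuple[str, ...] = CLASS_ORDER + ("artifact",)) -> pd.DataFrame:
    """Counts and percentages (half-up, 1 decimal) per temporal class.

    Accepts either a per-gene class series or precomputed per-class counts;
    percentages are over all predicted genes (so 47/201 -> 23.4).
    """
    if isinstance(classes, pd.Series):
        counts = classes.value_counts().to_dict()
    else:
        counts = dict(classes)
    total = sum(counts.values())
    rows = []
    for name in include:
        n = counts.get(name, 0)
        if name == "artifact" and n == 0 and name not in counts:
            continue
        rows.append({"class": name, "n_genes": n,
                     "percent": _pct1(100.0 * n / total) if total else 0.0})
    return pd.DataFrame(rows).set_index("class")
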