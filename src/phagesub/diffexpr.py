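"""Host differential expression: a negative-binomial conditional exact test
with a common dispersion, Benjamini-Hochberg FDR, and per-timepoint contrasts
against the uninfected 0-min group.

The test conditions on the pooled count of a gene across both groups: under a
shared NB(mean, phi) model, the group-A total given the pooled total has a
distribution whose mass can be enumerated, and the two-sided p-value sums the
probabilities of all splits at most as probable as the observed one. With
phi = 0 this reduces to the conditional binomial split test. Dispersion is a
method-of-moments common estimate; significance follows the p < 0.001 rule
with an FDR-threshold mode available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CountMatrix


def norm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample scaling factors: column totals rescaled to geometric mean 1."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).all():
        raise ValueError("all-zero count matrix")
    totals = totals.where(totals > 0, totals[totals > 0].min())
    logf = np.log(totals)
    return np.exp(logf - logf.mean())


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series,
                        factors: pd.Series | None = None,
                        min_mean: float = 5.0) -> float:
    """Common NB dispersion by method of moments on normalized counts.

    Per gene and replicated group: phi_g = (s^2 - mu) / mu^2, averaged over
    gene/group cells with mu > min_mean, floored at 0. Raises if no group has
    >= 2 replicates.
    """
    if factors is None:
        factors = norm_factors(counts)
    norm = counts.div(factors, axis=1)
    vals = []
    replicated = False
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        replicated = True
        sub = norm[cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = mu > min_mean
        vals.extend(((s2[ok] - mu[ok]) / mu[ok] ** 2).tolist())
    if not replicated:
        raise ValueError("no group has >= 2 replicates; supply an explicit dispersion")
    if not vals:
        return 0.0
    return max(0.0, float(np.mean(vals)))


def _group_total_logpmf(y: np.ndarray, mean: float, n: int, phi: float) -> np.ndarray:
    """log pmf of the total of n iid NB(mean, phi) counts (Poisson when phi=0)."""
    if phi <= 0:
        return stats.poisson.logpmf(y, n * mean)
    r = n / phi  # sum of n NB(r=1/phi) variables
    p = r / (r + n * mean)
    return stats.nbinom.logpmf(y, r, p)


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray, phi: float,
                  factors_a: np.ndarray | None = None,
                  factors_b: np.ndarray | None = None) -> float:
    """Two-sided conditional exact p-value for group A vs group B totals.

    Effective group sizes are the sums of normalization factors, so unequal
    library sizes shift the expected split proportionally.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    na = float(np.sum(factors_a)) if factors_a is not None else float(len(counts_a))
    nb = float(np.sum(factors_b)) if factors_b is not None else float(len(counts_b))
    ya = int(counts_a.sum())
    yb = int(counts_b.sum())
    s = ya + yb
    if s == 0:
        return 1.0
    mu = s / (na + nb)  # common per-effective-sample mean under the null
    y = np.arange(s + 1)
    logp = (_group_total_logpmf(y, mu, na, phi)
            + _group_total_logpmf(s - y, mu, nb, phi))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[ya]
    # two-sided: mass of splits at most as probable as observed
    pval = float(p[p <= obs * (1 + 1e-12)].sum())
    return min(1.0, pval)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class DEResult:
    table: pd.DataFrame       # gene, timepoint, logFC, pvalue, fdr, significant
    summary: pd.DataFrame     # per contrast: n_significant, pct up/down
    dispersion: float
    alpha: float


def call_de(cm: CountMatrix, baseline: float = 0.0, alpha: float = 0.001,
            use_fdr: bool = False, prior_count: float = 0.5,
            phi: float | None = None, experiment: str | None = None) -> DEResult:
    """Test every timepoint against the 0-min group.

    logFC is log2 of the (prior-count damped) normalized group means,
    timepoint over baseline. ``significant`` follows p < alpha by default
    (the published rule), or FDR < alpha with use_fdr=True. Only experiments
    containing a baseline group are testable; pass ``experiment`` to restrict.
    """
    meta = cm.meta
    if experiment is not None:
        meta = meta[meta["experiment"] == experiment]
    counts = cm.counts[meta.index]
    groups = meta["timepoint_min"]
    if baseline not in set(groups):
        raise ValueError(f"baseline group {baseline} min absent")
    factors = norm_factors(counts)
    if phi is None:
        phi = estimate_dispersion(counts, groups, factors)
    base_cols = groups.index[groups == baseline]
    rows = []
    for tp in sorted(set(groups) - {baseline}):
        cols = groups.index[groups == tp]
        fa = factors[base_cols].to_numpy()
        fb = factors[cols].to_numpy()
        a_norm = counts[base_cols].div(factors[base_cols], axis=1).mean(axis=1)
        b_norm = counts[cols].div(factors[cols], axis=1).mean(axis=1)
        logfc = np.log2((b_norm + prior_count) / (a_norm + prior_count))
        for gene in counts.index:
            p = nb_exact_test(counts.loc[gene, base_cols].to_numpy(),
                              counts.loc[gene, cols].to_numpy(), phi, fa, fb)
            rows.append({"gene": gene, "timepoint": tp,
                         "logFC": float(logfc[gene]), "pvalue": p})
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for tp in table["timepoint"].unique():
        sel = table["timepoint"] == tp
        table.loc[sel, "fdr"] = bh_fdr(table.loc[sel, "pvalue"].to_numpy())
    crit = table["fdr"] if use_fdr else table["pvalue"]
    table["significant"] = crit < alpha
    summ = []
    for tp, sub in table.groupby("timepoint"):
        sig = sub[sub["significant"]]
        n = len(sig)
        up = int((sig["logFC"] > 0).sum())
        summ.append({"timepoint": tp, "n_significant": n,
                     "pct_up": 100.0 * up / n if n else 0.0,
                     "pct_down": 100.0 * (n - up) / n if n else 0.0})
    return DEResult(table, pd.DataFrame(summ).set_index("timepoint"),
                    float(phi), alpha)
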