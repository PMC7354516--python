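"""NB exact test, dispersion estimation, BH FDR, and DE calling."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phagesub.diffexpr import (norm_factors, estimate_dispersion,
                               nb_exact_test, bh_fdr, call_de)
from phagesub.quant import CountMatrix


def test_norm_factors_contract():
    counts = pd.DataFrame({"a": [50, 50], "b": [50, 50], "c": [100, 100]})
    f = norm_factors(counts)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)
    assert f["c"] / f["a"] == pytest.approx(2.0)
    equal = pd.DataFrame({"a": [10, 10], "b": [10, 10]})
    assert np.allclose(norm_factors(equal), 1.0)
    with pytest.raises(ValueError):
        norm_factors(pd.DataFrame({"a": [0], "b": [0]}))


def test_dispersion_poisson_near_zero(rng):
    counts = pd.DataFrame(rng.poisson(100, size=(2000, 3)), columns=list("abc"))
    groups = pd.Series(["g"] * 3, index=list("abc"))
    phi = estimate_dispersion(counts, groups)
    assert 0.0 <= phi <= 0.05


def test_dispersion_recovers_nb_truth(rng):
    r, mu = 10, 100  # phi = 0.1
    counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mu), size=(2000, 6)),
                          columns=list("abcdef"))
    groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
    phi = estimate_dispersion(counts, groups)
    assert phi == pytest.approx(0.1, abs=0.05)


def test_dispersion_constant_counts_floor_zero():
    counts = pd.DataFrame({"a": [100, 7], "b": [100, 7], "c": [100, 7]})
    groups = pd.Series(["g"] * 3, index=list("abc"))
    assert estimate_dispersion(counts, groups) == 0.0


def test_dispersion_requires_replication():
    counts = pd.DataFrame({"a": [10], "b": [20]})
    groups = pd.Series(["g1", "g2"], index=list("ab"))
    with pytest.raises(ValueError):
        estimate_dispersion(counts, groups)


def test_identical_groups_give_p_one():
    assert nb_exact_test(np.array([10, 20, 30]), np.array([10, 20, 30]), 0.1) == 1.0


def test_swapping_groups_preserves_p(rng):
    for _ in range(10):
        a = rng.poisson(50, 3)
        b = rng.poisson(120, 3)
        assert nb_exact_test(a, b, 0.07) == pytest.approx(
            nb_exact_test(b, a, 0.07), rel=1e-9)


def oracle_binomial_conditional(ya, yb, na, nb):
    s = ya + yb
    p = na / (na + nb)
    pmf = stats.binom.pmf(np.arange(s + 1), s, p)
    return min(1.0, float(pmf[pmf <= pmf[ya] * (1 + 1e-12)].sum()))


def test_phi_zero_reduces_to_binomial_split(rng):
    for _ in range(20):
        a = rng.poisson(40, rng.integers(2, 5))
        b = rng.poisson(70, rng.integers(2, 5))
        want = oracle_binomial_conditional(int(a.sum()), int(b.sum()),
                                           len(a), len(b))
        assert nb_exact_test(a, b, 0.0) == pytest.approx(want, rel=1e-6)


def test_type_one_error_near_nominal(rng):
    r, mu = 10, 100
    a = rng.negative_binomial(r, r / (r + mu), size=(500, 3))
    b = rng.negative_binomial(r, r / (r + mu), size=(500, 3))
    pv = np.array([nb_exact_test(a[i], b[i], 0.1) for i in range(500)])
    assert 0.02 <= (pv < 0.05).mean() <= 0.08


def test_bh_hand_example_and_monotonicity(rng):
    got = bh_fdr([0.001, 0.01, 0.02, 0.04])
    assert np.allclose(got, [0.004, 0.02, 0.08 / 3, 0.04])
    assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
    p = np.sort(rng.random(30))
    q = bh_fdr(p)
    assert (np.diff(q) >= -1e-12).all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_statsmodels_on_random_vectors(rng):
    for n in (1, 5, 17, 50):
        p = rng.random(n)
        ours = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)


def test_agrees_with_edger_exact_test(rng, tmp_path):
    """Independent cross-check against edgeR's exactTest at fixed common
    dispersion on a small matrix."""
    counts = rng.negative_binomial(10, 10 / 110, size=(30, 6))
    f = tmp_path / "counts.tsv"
    np.savetxt(f, counts, fmt="%d", delimiter="\t")
    rcode = f"""
    suppressMessages(library(edgeR))
    x <- as.matrix(read.table("{f}"))
    y <- DGEList(counts=x, group=factor(c(1,1,1,2,2,2)))
    y$samples$norm.factors <- 1
    et <- exactTest(y, dispersion=0.1)
    cat(paste(et$table$PValue, collapse="\\n"))
    """
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                         text=True, check=True)
    edger_p = np.array([float(v) for v in out.stdout.strip().split()])
    ours = np.array([nb_exact_test(counts[i, :3], counts[i, 3:], 0.1)
                     for i in range(30)])
    assert np.corrcoef(ours, edger_p)[0, 1] > 0.99
    assert np.abs(ours - edger_p).max() < 0.1


def _synthetic_cm(rng, n_genes=60, n_de=8, mu=200, phi=0.05, lfc=2.0):
    r = 1 / phi
    groups = {"c1": 0.0, "c2": 0.0, "c3": 0.0, "t1": 30.0, "t2": 30.0, "t3": 30.0}
    de_genes = [f"g{i:03d}" for i in range(n_de)]
    rows = {}
    for i in range(n_genes):
        gid = f"g{i:03d}"
        mu_t = mu * (2 ** lfc if gid in de_genes else 1.0)
        rows[gid] = np.concatenate([
            rng.negative_binomial(r, r / (r + mu), 3),
            rng.negative_binomial(r, r / (r + mu_t), 3)])
    counts = pd.DataFrame(rows, index=list(groups)).T
    meta = pd.DataFrame({"experiment": "e", "timepoint_min": pd.Series(groups),
                         "replicate": [1, 2, 3, 1, 2, 3],
                         "library_size": counts.sum(axis=0) + 10})
    return CountMatrix(counts, meta), de_genes


def test_call_de_finds_planted_changes(rng):
    cm, de_genes = _synthetic_cm(rng)
    res = call_de(cm, alpha=0.001)
    table = res.table.set_index("gene")
    hit = table.loc[de_genes, "significant"].mean()
    assert hit >= 0.8
    null = table.drop(index=de_genes)
    assert int(null["significant"].sum()) <= 3
    # up/down bookkeeping
    sig = res.table[res.table.significant]
    for tp, row in res.summary.iterrows():
        sub = sig[sig.timepoint == tp]
        assert len(sub) == row["n_significant"]
        assert row["pct_up"] + row["pct_down"] == pytest.approx(100.0 if len(sub) else 0.0)


def test_call_de_logfc_sign_and_prior(rng):
    cm, de_genes = _synthetic_cm(rng, lfc=-2.0)
    res = call_de(cm, alpha=0.001)
    table = res.table.set_index("gene")
    assert (table.loc[de_genes, "logFC"] < -1).all()
    assert np.isfinite(table["logFC"]).all()


def test_call_de_requires_baseline(rng):
    cm, _ = _synthetic_cm(rng)
    cm.meta["timepoint_min"] = [5.0, 5.0, 5.0, 30.0, 30.0, 30.0]
    with pytest.raises(ValueError):
        call_de(cm)
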