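import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st_h

from mireqtl.assoc import (
    BootstrapSpec,
    bh_fdr,
    bootstrap_trend_p,
    build_design,
    differential_trend,
    fit_trend,
    genotype_class_summary,
    paired_bootstrap_ttest,
)


def _genotypes(rng, n, maf=0.3):
    p = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
    g = rng.choice(3, size=n, p=p)
    while np.unique(g).size < 2:
        g = rng.choice(3, size=n, p=p)
    return g


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.normal(65, 9.5, n),
            "sex": rng.choice(["male", "female"], n),
            "center": rng.choice(["utah", "kaiser"], n),
        }
    )


# ---------------------------------------------------------------------------
# fit_trend


def test_constant_outcome_zero_beta(rng):
    g = _genotypes(rng, 80)
    fit = fit_trend(np.full(80, 3.7), g, _covariates(rng, 80))
    assert abs(fit.beta) < 1e-12


def test_noiseless_trend_recovered(rng):
    g = _genotypes(rng, 120)
    y = 0.7 * g + 1.0
    fit = fit_trend(y, g, None)
    assert fit.beta == pytest.approx(0.7, abs=1e-10)


def test_fit_matches_statsmodels_ols(rng):
    """Coefficients and SE agree with an independent least-squares routine
    on a random 50 x 5 design."""
    n = 50
    g = _genotypes(rng, n)
    cov = pd.DataFrame(
        {"age": rng.normal(65, 9, n), "x1": rng.normal(size=n), "x2": rng.normal(size=n)}
    )
    y = 0.4 * g + 0.02 * cov["age"].to_numpy() + rng.normal(size=n)
    fit = fit_trend(y, g, cov)
    X, _ = build_design(g, cov)
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-9)
    assert fit.se_beta == pytest.approx(float(ref.bse[1]), rel=1e-9)


def test_rank_deficient_design_names_columns(rng):
    n = 60
    g = _genotypes(rng, n)
    cov = pd.DataFrame({"age": rng.normal(65, 9, n)})
    cov["age_copy"] = cov["age"]
    with pytest.raises(ValueError, match="age_copy"):
        fit_trend(rng.normal(size=n), g, cov)


def test_degenerate_genotype_rejected(rng):
    with pytest.raises(ValueError, match="distinct"):
        fit_trend(rng.normal(size=30), np.zeros(30), None)


# ---------------------------------------------------------------------------
# bootstrap trend p


def test_strong_signal_attains_minimum_p(rng):
    n, B = 200, 999
    g = _genotypes(rng, n)
    y = 2.0 * g + rng.normal(0, 0.1, n)
    res = bootstrap_trend_p(y, g, None, BootstrapSpec(n_boot=B, seed=1))
    assert res["p_raw"] == pytest.approx(2.0 / (B + 1))


def test_bootstrap_seeded_reproducible(rng):
    n = 100
    g = _genotypes(rng, n)
    y = 0.2 * g + rng.normal(size=n)
    cov = _covariates(np.random.default_rng(1), n)
    a = bootstrap_trend_p(y, g, cov, BootstrapSpec(n_boot=500, seed=42))
    b = bootstrap_trend_p(y, g, cov, BootstrapSpec(n_boot=500, seed=42))
    assert a == b
    assert a["p_raw"] > 0  # add-one smoothing forbids exact zero


def test_residual_bootstrap_variant(rng):
    n = 150
    g = _genotypes(rng, n)
    y = 0.5 * g + rng.normal(size=n)
    res = bootstrap_trend_p(
        y, g, None, BootstrapSpec(n_boot=500, seed=3, method="residual")
    )
    assert 0 < res["p_raw"] <= 1
    assert res["boot_sd"] > 0


def test_rare_genotype_triggers_redraws(rng):
    n = 40
    g = np.zeros(n)
    g[:2] = 1  # rare carriers: many replicates will miss them
    y = rng.normal(size=n)
    res = bootstrap_trend_p(y, g, None, BootstrapSpec(n_boot=400, seed=5))
    assert res["n_redrawn"] > 0
    assert 0 < res["p_raw"] <= 1


def test_bootstrap_spec_validation():
    with pytest.raises(ValueError):
        BootstrapSpec(n_boot=10)
    with pytest.raises(ValueError):
        BootstrapSpec(method="parametric")


# ---------------------------------------------------------------------------
# differential trend


def test_identical_tissues_null(rng):
    n = 120
    g = _genotypes(rng, n)
    y = rng.normal(size=n)
    res = differential_trend(y, y, g, None, BootstrapSpec(n_boot=500, seed=2))
    assert res["beta"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_raw"] > 0.9


def test_sign_flip_symmetry(rng):
    n = 150
    g = _genotypes(rng, n)
    y_n = rng.normal(size=n)
    y_t = y_n + 0.4 * g + rng.normal(0, 0.5, n)
    spec = BootstrapSpec(n_boot=800, seed=9)
    fwd = differential_trend(y_t, y_n, g, None, spec)
    rev = differential_trend(y_n, y_t, g, None, spec)
    assert fwd["beta"] == pytest.approx(-rev["beta"], rel=1e-12)
    assert fwd["p_raw"] == rev["p_raw"]


def test_unpaired_individuals_dropped(rng):
    n = 100
    g = _genotypes(rng, n).astype(float)
    y_n = rng.normal(size=n)
    y_t = y_n + 0.2
    y_t[:5] = np.nan
    res = differential_trend(y_t, y_n, g, None, BootstrapSpec(n_boot=300, seed=1))
    assert res["n_dropped"] == 5
    assert res["n"] == 95


# ---------------------------------------------------------------------------
# paired bootstrap t-test


def test_paired_identical_tissues_degenerate(rng):
    y = rng.normal(size=50)
    res = paired_bootstrap_ttest(y, y, BootstrapSpec(n_boot=300, seed=0))
    assert res.degenerate
    assert res.p_value == 1.0
    assert res.t_stat == 0.0


def test_paired_large_effect_minimum_p(rng):
    n, B = 100, 999
    y_n = rng.normal(0, 0.3, n)
    y_t = y_n + 1.0 + rng.normal(0, 0.3, n)
    res = paired_bootstrap_ttest(y_t, y_n, BootstrapSpec(n_boot=B, seed=4))
    assert res.p_value == pytest.approx(1.0 / (B + 1))


def test_paired_test_empirical_size(rng):
    """Under a null generator the rejection rate at 0.05 stays within
    3 binomial SDs of nominal."""
    ndata, n, B = 400, 50, 300
    rej = 0
    for i in range(ndata):
        d_rng = np.random.default_rng(10_000 + i)
        y_n = d_rng.normal(size=n)
        y_t = y_n + d_rng.normal(0, 0.5, size=n)  # paired, no mean shift
        res = paired_bootstrap_ttest(y_t, y_n, BootstrapSpec(n_boot=B, seed=20_000 + i))
        rej += res.p_value < 0.05
    rate = rej / ndata
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / ndata)


def test_paired_requires_three_pairs():
    with pytest.raises(ValueError, match="3"):
        paired_bootstrap_ttest([1.0, 2.0], [1.0, 2.5])


# ---------------------------------------------------------------------------
# BH FDR


def bh_bruteforce(p):
    """Adjusted p_i = smallest level q at which the BH step-up procedure
    rejects H_i; scans every candidate threshold."""
    m = len(p)
    cands = sorted({pj * m / k for pj in p for k in range(1, m + 1)} | {1.0})
    ps = sorted(p)
    adj = []
    for i in range(m):
        best = 1.0
        for q in cands:
            # evaluate rejection at q inflated by an epsilon so that the
            # infimum threshold itself counts as attained despite rounding
            qe = q * (1 + 1e-9) + 1e-15
            k = 0
            for r in range(m, 0, -1):
                if ps[r - 1] <= qe * r / m:
                    k = r
                    break
            if k > 0 and p[i] <= ps[k - 1]:
                best = min(best, q)
        adj.append(min(best, 1.0))
    return np.array(adj)


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_fdr([0.123]), [0.123])


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_elementwise_dominance_and_order(rng):
    p = rng.uniform(size=25)
    q = bh_fdr(p)
    assert (q >= p - 1e-15).all()
    # monotone in rank: sorting p sorts q the same way
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_rejects_invalid_input():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_fdr([[0.1, 0.2]])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    p=st_h.lists(
        st_h.sampled_from([0.001, 0.02, 0.3, 0.7, 1.0]), min_size=1, max_size=10
    )
)
def test_bh_matches_bruteforce_threshold_scan(p):
    np.testing.assert_allclose(bh_fdr(p), bh_bruteforce(p), atol=1e-12)


# ---------------------------------------------------------------------------
# descriptives


def test_genotype_class_summary(rng):
    g = np.array([0, 0, 1, 1, 1, 2])
    sig = np.array([2.0, 0.0, 4.0, 4.0, 0.0, 10.0])
    out = genotype_class_summary(sig, g)
    assert list(out["n"]) == [2, 3, 1]
    assert out.loc[0, "mean"] == pytest.approx(1.0)
    assert out.loc[1, "pct_zero"] == pytest.approx(100 / 3)
    missing = genotype_class_summary(sig[:5], g[:5])
    assert missing.loc[2, "n"] == 0 and np.isnan(missing.loc[2, "mean"])
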