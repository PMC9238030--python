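import numpy as np
import pytest
from scipy import stats

from extremeprs import (AssociationError, cluster_robust_covariance,
                        compare_allele_frequencies, fisher_exact_two_sided,
                        fit_logistic, harmonize, spearman_correlation,
                        welch_t_test)

from conftest import make_gt, make_weight


def _sim_logistic(rng, n=200, beta=(0.2, 0.8, -0.5)):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta))))
    y = (rng.random(n) < p).astype(float)
    return y, X


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def test_intercept_only_closed_forms():
    y = np.array([0.0, 1.0] * 25)
    fit = fit_logistic(y, np.ones((50, 1)))
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-10)

    y = np.array([0.0] + [1.0] * 3).repeat(10)
    fit = fit_logistic(y, np.ones((40, 1)))
    assert fit.coef[0] == pytest.approx(np.log(3.0), abs=1e-8)


def test_coefficients_match_statsmodels_oracle(rng):
    import statsmodels.api as sm
    y, X = _sim_logistic(rng)
    fit = fit_logistic(y, X)
    oracle = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12)
    assert np.allclose(fit.coef, oracle.params, atol=1e-6)
    assert fit.converged


def test_rank_deficient_design_names_the_column(rng):
    y, X = _sim_logistic(rng, n=50)
    X = np.column_stack([X, X[:, 1]])
    with pytest.raises(AssociationError, match="x3"):
        fit_logistic(y, X)


def test_perfect_separation_is_flagged():
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
    y = (x > 0).astype(float)
    X = np.column_stack([np.ones(6), x])
    with pytest.warns(UserWarning):
        fit = fit_logistic(y, X)
    assert fit.separation


# ---------------------------------------------------------------------------
# Cluster-robust covariance
# ---------------------------------------------------------------------------

def test_singleton_clusters_reduce_to_hc_covariance(rng):
    """With every observation its own cluster the sandwich equals the
    HC-type covariance with small-sample factor n/(n-1)."""
    y, X = _sim_logistic(rng)
    fit = fit_logistic(y, X)
    res = cluster_robust_covariance(fit, np.arange(len(y)))
    n = len(y)
    A_inv = np.linalg.inv(fit.info)
    hc0 = A_inv @ (fit.scores.T @ fit.scores) @ A_inv
    assert np.allclose(res.cov, hc0 * n / (n - 1), atol=0, rtol=1e-12)


def test_cluster_covariance_matches_statsmodels_oracle(rng):
    import statsmodels.api as sm
    y, X = _sim_logistic(rng, n=300)
    groups = np.repeat(np.arange(75), 4)
    fit = fit_logistic(y, X)
    res = cluster_robust_covariance(fit, groups)
    oracle = sm.Logit(y, X).fit(disp=0, cov_type="cluster",
                                cov_kwds={"groups": groups})
    # statsmodels applies an extra (n-1)/(n-k) degrees-of-freedom factor
    n, k = X.shape
    rescaled = np.asarray(oracle.cov_params()) * (n - k) / (n - 1)
    assert np.allclose(res.cov, rescaled, rtol=1e-6)


def test_duplicating_observations_and_clusters(rng):
    y, X = _sim_logistic(rng)
    groups = np.repeat(np.arange(50), 4)
    fit = fit_logistic(y, X)
    res = cluster_robust_covariance(fit, groups)

    y2, X2 = np.tile(y, 2), np.tile(X, (2, 1))
    groups2 = np.tile(groups, 2)  # duplicates stay in their original cluster
    fit2 = fit_logistic(y2, X2)
    res2 = cluster_robust_covariance(fit2, groups2)
    assert np.allclose(fit2.coef, fit.coef, atol=1e-7)
    # naive (inverse-information) SEs shrink by sqrt(2)...
    naive_ratio = np.sqrt(np.diag(np.linalg.inv(fit2.info))
                          / np.diag(np.linalg.inv(fit.info)))
    assert np.allclose(naive_ratio, 1.0 / np.sqrt(2), atol=1e-6)
    # ...while cluster-robust SEs stay within 5% of the original
    ratio = res2.table["se"].to_numpy() / res.table["se"].to_numpy()
    assert np.all(np.abs(ratio - 1.0) < 0.05)


def test_association_table_invariants(rng):
    y, X = _sim_logistic(rng)
    res = cluster_robust_covariance(fit_logistic(y, X), np.arange(len(y)))
    t = res.table
    assert ((t["ci_low"] <= t["or"]) & (t["or"] <= t["ci_high"])).all()
    assert ((t["p"] > 0) & (t["p"] <= 1)).all()
    assert np.allclose(np.exp(t["coef"]), t["or"], rtol=1e-12)


def test_single_cluster_is_fatal(rng):
    y, X = _sim_logistic(rng, n=30)
    with pytest.raises(AssociationError, match="clusters"):
        cluster_robust_covariance(fit_logistic(y, X), np.zeros(30))


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

def test_welch_identical_samples():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)


def test_welch_matches_textbook_formula():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = welch_t_test(a, b)
    sa, sb = a.var(ddof=1) / 3, b.var(ddof=1) / 5
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / 2 + sb ** 2 / 4)
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.df == pytest.approx(df, abs=1e-10)
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-10)
    scipy_res = stats.ttest_ind(a, b, equal_var=False)
    assert res.t == pytest.approx(scipy_res.statistic, abs=1e-10)
    assert res.p == pytest.approx(scipy_res.pvalue, abs=1e-10)


def test_welch_antisymmetry(rng):
    a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=15)
    r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
    assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert spearman_correlation(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman_correlation(x, -x ** 3).rho == pytest.approx(-1.0)


def test_spearman_with_ties_matches_rank_then_pearson_oracle(rng):
    x = rng.integers(0, 5, size=40).astype(float)
    y = rng.integers(0, 5, size=40).astype(float)
    res = spearman_correlation(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)  # mid-ranks
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert res.rho == pytest.approx(oracle, abs=1e-12)


def test_spearman_ci_is_a_valid_interval(rng):
    x = rng.normal(size=50)
    y = x + rng.normal(scale=0.3, size=50)
    res = spearman_correlation(x, y)
    lo, hi = res.ci95
    assert -1 <= lo < res.rho < hi <= 1
    # Fisher-z oracle
    half = 1.96 / np.sqrt(50 - 3)
    assert lo == pytest.approx(np.tanh(np.arctanh(res.rho) - half))
    with pytest.raises(ValueError, match="constant"):
        spearman_correlation(np.ones(10), y[:10])


# ---------------------------------------------------------------------------
# Fisher exact allele-frequency screen
# ---------------------------------------------------------------------------

def test_fisher_identical_counts_give_p_one():
    assert fisher_exact_two_sided(10, 10, 10, 10) == pytest.approx(1.0)


def test_fisher_matches_full_enumeration_oracle():
    """Complete-separation table checked against explicit hypergeometric
    enumeration of all tables with the same margins."""
    from math import comb
    a, b, c, d = 10, 0, 0, 10
    n, r1, c1 = 20, 10, 10
    probs = [comb(r1, k) * comb(n - r1, c1 - k) / comb(n, c1)
             for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)]
    obs = comb(r1, a) * comb(n - r1, c1 - a) / comb(n, c1)
    expected = sum(p for p in probs if p <= obs * (1 + 1e-7))
    assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(expected, rel=1e-12)


def test_fisher_matches_scipy_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 30, size=4)
        ours = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
        theirs = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)


def test_allele_frequency_screen_table(rng):
    weights = [make_weight("rs1", "A", "G"), make_weight("rs2", "C", "T")]
    # rs1 identical frequencies; rs2 monomorphic in both groups
    gt = make_gt([["AG", "CC"], ["AG", "CC"], ["AG", "CC"], ["AG", "CC"]],
                 snp_ids=["rs1", "rs2"])
    labels = ["X", "X", "Y", "Y"]
    out = compare_allele_frequencies(harmonize(weights, gt), labels)
    assert out["p"].to_numpy() == pytest.approx([1.0, 1.0])
    assert not out["significant"].any()
    assert np.allclose(out["p_bonferroni"], np.minimum(1.0, out["p"] * 2))


def test_allele_frequency_screen_rejects_imputed_dosages():
    weights = [make_weight("rs1", "A", "G")]
    gt = make_gt([["AG"], ["00"], ["AA"]], snp_ids=["rs1"])
    from extremeprs import impute_missing
    hd = impute_missing(harmonize(weights, gt))
    with pytest.raises(ValueError, match="integer"):
        compare_allele_frequencies(hd, ["X", "Y", "X"])
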