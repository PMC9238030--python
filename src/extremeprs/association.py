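"""Statistics for the extreme-phenotype design.

Centerpiece: binomial logistic regression of early-diagnosis (ED=1) versus
late/no-diagnosis (LD=0) status on the standardized PRS and covariates, with
a cluster-robust sandwich variance clustered on family ID to account for
related carriers.  Also here: Welch's unequal-variance t-test, Spearman rank
correlation with a Fisher-z confidence interval, and a Bonferroni-corrected
two-sided Fisher exact screen for allele-frequency differences between
recruitment sources.

The sandwich is V = A^-1 B A^-1 with A the observed information and B the sum
over clusters of outer products of within-cluster summed score vectors,
scaled by the finite-sample factor m/(m-1) for m clusters.  With singleton
clusters this reduces exactly to the HC-type heteroskedasticity-robust
covariance with factor n/(n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

Z_95 = 1.96  # two-sided 95% normal quantile used for Wald intervals


class AssociationError(RuntimeError):
    """Fatal model failure (rank deficiency, degenerate clustering, ...)."""


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with per-observation scores."""

    coef: np.ndarray
    colnames: list[str]
    X: np.ndarray
    y: np.ndarray
    fitted: np.ndarray           # P(y=1 | x)
    scores: np.ndarray           # (n, k) rows x_i * (y_i - p_i)
    info: np.ndarray             # observed information X' W X
    converged: bool
    n_iter: int
    separation: bool


def _check_rank(X: np.ndarray, colnames: Sequence[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [colnames[j] for j in np.flatnonzero(diag <= tol)]
    if bad:
        raise AssociationError(f"design matrix is rank deficient; collinear column(s): {bad}")


def fit_logistic(y: np.ndarray, X: np.ndarray,
                 colnames: Sequence[str] | None = None,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Fit a binomial logistic model by iteratively reweighted least squares.

    Convergence when the largest absolute coefficient change drops below
    ``tol``.  Perfect or quasi-perfect separation is flagged (every fitted
    probability within 1e-6 of its outcome), never silently ignored.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("y must be 1-D and aligned with the rows of X")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in y or X")
    n, k = X.shape
    colnames = list(colnames) if colnames is not None else [f"x{j}" for j in range(k)]
    _check_rank(X, colnames)

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        A = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        delta = np.linalg.solve(A, grad)
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    separation = bool(np.all(np.abs(y - p) < 1e-6))
    if separation:
        warnings.warn("(quasi-)perfect separation detected; estimates unreliable")
    if not converged:
        warnings.warn(f"IRLS did not converge in {max_iter} iterations")
    w = np.clip(p * (1.0 - p), 1e-10, None)
    return LogisticFit(
        coef=beta, colnames=colnames, X=X, y=y, fitted=p,
        scores=X * (y - p)[:, None], info=X.T @ (X * w[:, None]),
        converged=converged, n_iter=it, separation=separation,
    )


# ---------------------------------------------------------------------------
# Cluster-robust sandwich variance
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Coefficient table with cluster-robust inference.

    ``table`` columns: term, coef, se, or (exp(coef)), ci_low, ci_high
    (Wald, exponentiated), p (two-sided z-test).
    """

    table: pd.DataFrame
    cov: np.ndarray
    n: int
    n_clusters: int
    converged: bool
    separation: bool

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def cluster_robust_covariance(fit: LogisticFit,
                              cluster_ids: Sequence) -> AssociationResult:
    """Sandwich covariance with scores summed within family clusters."""
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.shape[0] != fit.X.shape[0]:
        raise ValueError("cluster_ids must align with the model rows")
    uniq, inv = np.unique(cluster_ids, return_inverse=True)
    m = uniq.size
    if m < 2:
        raise AssociationError("clustered variance needs >= 2 clusters")
    k = fit.X.shape[1]
    cluster_scores = np.zeros((m, k))
    np.add.at(cluster_scores, inv, fit.scores)
    B = cluster_scores.T @ cluster_scores
    A_inv = np.linalg.inv(fit.info)
    V = (m / (m - 1.0)) * A_inv @ B @ A_inv
    se = np.sqrt(np.diag(V))
    z = fit.coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "term": fit.colnames,
        "coef": fit.coef,
        "se": se,
        "or": np.exp(fit.coef),
        "ci_low": np.exp(fit.coef - Z_95 * se),
        "ci_high": np.exp(fit.coef + Z_95 * se),
        "p": np.maximum(p, np.finfo(float).tiny),
    })
    return AssociationResult(table=table, cov=V, n=fit.X.shape[0], n_clusters=m,
                             converged=fit.converged, separation=fit.separation)


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------

class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        raise ValueError("zero variance in both samples with unequal means")
    sa, sb = va / a.size, vb / b.size
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# Spearman correlation with Fisher-z CI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci95: tuple[float, float]
    n: int


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho (mid-ranks for ties) with a Fisher-z 95% CI.

    The CI back-transforms atanh(rho) +/- 1.96/sqrt(n-3) and is clipped to
    [-1, 1]; for |rho| = 1 the interval degenerates to the point itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Spearman correlation undefined for a constant input")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, (rho, rho), int(x.size))
    z = np.arctanh(rho)
    half = Z_95 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(rho, (float(lo), float(hi)), int(x.size))


# ---------------------------------------------------------------------------
# Fisher exact allele-frequency screen
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric point masses of every table with the same margins
    whose probability does not exceed the observed table's (the common
    two-sided convention), with a 1+1e-7 relative tolerance on the
    comparison to absorb floating-point noise.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
              + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
              - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    pmf = np.exp(logpmf)
    observed = pmf[np.searchsorted(k, a)]
    return float(min(1.0, pmf[pmf <= observed * (1.0 + 1e-7)].sum()))


def compare_allele_frequencies(hd, source_labels: Sequence) -> pd.DataFrame:
    """Per-SNP Fisher exact comparison of allele counts between two groups.

    ``hd`` is a pre-imputation :class:`~extremeprs.scoring.HarmonizedDosages`
    (integer dosages, NaN for missing); ``source_labels`` assigns each sample
    to one of exactly two groups (e.g., recruitment source).  Returns one row
    per SNP with the raw p, the Bonferroni-adjusted p over the SNPs tested,
    and a significance flag at adjusted p < 0.05.
    """
    labels = np.asarray(source_labels)
    if labels.shape[0] != len(hd.sample_ids):
        raise ValueError("source_labels must align with samples")
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups.size}")
    dosages = hd.dosages
    observed = ~np.isnan(dosages)
    if not np.all(np.rint(dosages[observed]) == dosages[observed]):
        raise ValueError("dosages must be integers (run before imputation)")
    in_g1 = labels == groups[0]
    rows = []
    for j, w in enumerate(hd.weights):
        col, obs = dosages[:, j], observed[:, j]
        eff1 = int(np.nansum(col[in_g1 & obs]))
        tot1 = int(2 * (in_g1 & obs).sum())
        eff2 = int(np.nansum(col[~in_g1 & obs]))
        tot2 = int(2 * (~in_g1 & obs).sum())
        p = fisher_exact_two_sided(eff1, tot1 - eff1, eff2, tot2 - eff2)
        rows.append({"snp_id": w.snp_id,
                     f"effect_count_{groups[0]}": eff1, f"total_{groups[0]}": tot1,
                     f"effect_count_{groups[1]}": eff2, f"total_{groups[1]}": tot2,
                     "p": p})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * n_tests)
    out["significant"] = out["p_bonferroni"] < 0.05
    return out
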