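"""Independent, deliberately naive reference implementations used as
oracles in tests. Nothing here shares code with the package: indicators
are plain-Python loops over the defining formulas, the pedigree
relationship oracle counts identity-by-descent over gene-dropping
replicates, the REML oracle evaluates the restricted likelihood with dense
matrix algebra on a fine grid, and the ANOVA oracle fits full and reduced
models by least squares."""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# resilience indicators
# ---------------------------------------------------------------------------


def naive_ln_variance(values) -> float:
    xs = [float(v) for v in values if not math.isnan(v)]
    n = len(xs)
    if n < 2:
        return math.nan
    mean = sum(xs) / n
    ss = sum((x - mean) ** 2 for x in xs)
    var = ss / (n - 1)
    if var <= 0:
        return math.nan
    return math.log(var)


def naive_skewness(values) -> float:
    xs = [float(v) for v in values if not math.isnan(v)]
    n = len(xs)
    if n < 3:
        return math.nan
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    if m2 <= 0:
        return math.nan
    return m3 / m2**1.5


def naive_rauto(values) -> float:
    xs = [float(v) for v in values if not math.isnan(v)]
    n = len(xs)
    if n < 3:
        return math.nan
    mean = sum(xs) / n
    denom = sum((x - mean) ** 2 for x in xs)
    if denom <= 0:
        return math.nan
    num = sum((xs[t] - mean) * (xs[t + 1] - mean) for t in range(n - 1))
    return num / denom


# ---------------------------------------------------------------------------
# pedigree relationships by gene-dropping Monte Carlo
# ---------------------------------------------------------------------------


def amatrix_gene_drop_mc(
    parents: np.ndarray, n_loci: int = 50_000, seed: int = 0
) -> np.ndarray:
    """Estimate additive relationships as expected genome sharing: drop
    uniquely labelled founder alleles through the pedigree at ``n_loci``
    independent loci and count identity-by-descent.

    a_ij = 2 * coancestry(i, j); a_ii = 1 + P(the two alleles of i are IBD).
    """
    rng = np.random.default_rng(seed)
    n = parents.shape[0]
    alleles = np.empty((n, 2, n_loci), dtype=np.int64)
    next_label = 0
    for i in range(n):
        s, d = parents[i]
        for slot, p in enumerate((s, d)):
            if p < 0:
                alleles[i, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, n_loci)
                alleles[i, slot] = alleles[p, pick, np.arange(n_loci)]
    A = np.empty((n, n))
    for i in range(n):
        A[i, i] = 1.0 + np.mean(alleles[i, 0] == alleles[i, 1])
        for j in range(i):
            share = sum(
                np.mean(alleles[i, a] == alleles[j, b]) for a in (0, 1) for b in (0, 1)
            )
            A[i, j] = A[j, i] = share / 2.0
    return A


# ---------------------------------------------------------------------------
# REML by dense algebra on a grid
# ---------------------------------------------------------------------------


def dense_reml_loglik(y, X, K, gamma) -> float:
    """Restricted log-likelihood with sigma_e^2 profiled out, computed with
    explicit dense matrices (no eigendecomposition)."""
    n, p = X.shape
    V0 = gamma * K + np.eye(n)
    V0i = np.linalg.inv(V0)
    XtVX = X.T @ V0i @ X
    beta = np.linalg.solve(XtVX, X.T @ V0i @ y)
    r = y - X @ beta
    rss = float(r @ V0i @ r)
    sigma_e2 = rss / (n - p)
    _, logdet_v0 = np.linalg.slogdet(V0)
    _, logdet_x = np.linalg.slogdet(XtVX)
    return -0.5 * (
        (n - p) * math.log(2 * math.pi * sigma_e2)
        + (n - p)
        + logdet_v0
        + logdet_x
    )


def grid_reml_oracle(y, X, K, n_points: int = 4001, gamma_max: float = 100.0):
    """Maximise the dense restricted likelihood over a fine gamma grid.
    Returns (gamma_hat, logL_hat)."""
    grid = np.concatenate([[0.0], np.geomspace(1e-6, gamma_max, n_points)])
    vals = [dense_reml_loglik(y, X, K, g) for g in grid]
    k = int(np.argmax(vals))
    return float(grid[k]), float(vals[k])


# ---------------------------------------------------------------------------
# fixed-effects ANOVA partial F
# ---------------------------------------------------------------------------


def anova_partial_f(y, X_base, snp_calls):
    """Ordinary least-squares incremental F for a categorical SNP factor
    added to a base design. Returns (F, df_num, df_den, p)."""
    from scipy.stats import f as f_dist

    classes = sorted(set(snp_calls))
    counts = {c: list(snp_calls).count(c) for c in classes}
    ref = max(classes, key=lambda c: (counts[c], -c))
    dummies = np.column_stack(
        [(np.asarray(snp_calls) == c).astype(float) for c in classes if c != ref]
    )
    X_full = np.column_stack([X_base, dummies])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(X_base), rss(X_full)
    q = dummies.shape[1]
    df_den = len(y) - X_full.shape[1]
    F = ((rss_r - rss_f) / q) / (rss_f / df_den)
    return F, q, df_den, float(f_dist.sf(F, q, df_den))
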