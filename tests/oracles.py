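"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by a route deliberately
different from the package implementation (dense solves, explicit
enumeration, naive double loops) so that agreement is evidence of
correctness rather than repetition.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import t as t_dist


def hwe_exact_enumeration(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact HWE p-value by full enumeration in rational arithmetic."""
    n = n_hom_minor + n_het + n_hom_major
    n_a = 2 * n_hom_minor + n_het
    n_b = 2 * n - n_a

    def prob(het: int) -> Fraction:
        hom_minor = (n_a - het) // 2
        hom_major = n - het - hom_minor
        num = (
            math.factorial(n)
            * 2**het
            * math.factorial(n_a)
            * math.factorial(n_b)
        )
        den = (
            math.factorial(hom_minor)
            * math.factorial(het)
            * math.factorial(hom_major)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def grm_double_loop(dosages: np.ndarray) -> np.ndarray:
    """VanRaden G by an explicit O(n^2 m) double loop with mean imputation."""
    X = dosages.copy()
    n, m = X.shape
    for j in range(m):
        col = X[:, j]
        col[np.isnan(col)] = np.nanmean(col)
    p = X.mean(axis=0) / 2.0
    keep = [j for j in range(m) if 0 < p[j] < 1]
    denom = 2.0 * sum(p[j] * (1 - p[j]) for j in keep)
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in keep:
                acc += (X[i, j] - 2 * p[j]) * (X[k, j] - 2 * p[j])
            G[i, k] = acc / denom
    return G


def reml_loglik_dense(delta: float, y: np.ndarray, X: np.ndarray, K: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma_g2, via dense solves.

    Uses log|V|, log|X'V^-1X| and the projection quadratic form rather
    than any eigendecomposition of the projected kinship.
    """
    n, q = X.shape
    nq = n - q
    V = K + delta * np.eye(n)
    sign_v, logdet_v = np.linalg.slogdet(V)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    sign_x, logdet_x = np.linalg.slogdet(XtVinvX)
    sign_xx, logdet_xx = np.linalg.slogdet(X.T @ X)
    b = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    ypy = float(y @ Vinv_y - (X.T @ Vinv_y) @ b)
    return 0.5 * (
        nq * math.log(nq / (2 * math.pi))
        - nq
        - nq * math.log(ypy)
        - (logdet_v + logdet_x - logdet_xx)
    )


def emma_delta_grid(y, X, K, n_points=10_000, lo=1e-5, hi=1e5):
    """Brute-force delta estimate: dense-likelihood grid plus golden refinement."""
    grid = np.logspace(np.log10(lo), np.log10(hi), n_points)
    lls = np.array([reml_loglik_dense(d, y, X, K) for d in grid])
    i = int(np.argmax(lls))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_points - 1)]
    # golden-section refinement of the same dense likelihood
    invphi = (math.sqrt(5) - 1) / 2
    la, lb = math.log(a), math.log(b)
    c = lb - invphi * (lb - la)
    d = la + invphi * (lb - la)
    fc = reml_loglik_dense(math.exp(c), y, X, K)
    fd = reml_loglik_dense(math.exp(d), y, X, K)
    for _ in range(60):
        if fc > fd:
            lb, d, fd = d, c, fc
            c = lb - invphi * (lb - la)
            fc = reml_loglik_dense(math.exp(c), y, X, K)
        else:
            la, c, fc = c, d, fd
            d = la + invphi * (lb - la)
            fd = reml_loglik_dense(math.exp(d), y, X, K)
    return math.exp((la + lb) / 2)


def gls_scan_dense(y, X, K, dosages, sigma_g2, sigma_e2):
    """Per-SNP GLS with an explicit V^{-1} solve; returns (beta, p, mrss)."""
    n = len(y)
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    m = dosages.shape[1]
    betas = np.empty(m)
    pvals = np.empty(m)
    mrss = np.empty(m)
    for j in range(m):
        g = dosages[:, j].copy()
        g[np.isnan(g)] = np.nanmean(g)
        C = np.column_stack([X, g])
        A = C.T @ Vinv @ C
        b = np.linalg.solve(A, C.T @ Vinv @ y)
        r = y - C @ b
        quad = float(r @ Vinv @ r)
        df = n - C.shape[1]
        sigma2 = quad / df
        se = math.sqrt(sigma2 * np.linalg.inv(A)[-1, -1])
        tstat = b[-1] / se
        betas[j] = b[-1]
        pvals[j] = 2 * t_dist.sf(abs(tstat), df)
        mrss[j] = quad
    return betas, pvals, mrss


def snp_blup_gebv(y, X, dosages, delta, ridge=0.0):
    """Ridge-regression (SNP-BLUP) breeding values on the normalized M.

    With M column-centered at 2p and globally scaled so M M' equals the
    VanRaden GRM, GBLUP on the raw GRM equals u = M M'(M M' + delta I)^-1
    (y - X beta_gls).
    """
    Xd = dosages.copy()
    for j in range(Xd.shape[1]):
        col = Xd[:, j]
        col[np.isnan(col)] = np.nanmean(col)
    p = Xd.mean(axis=0) / 2.0
    c = math.sqrt(float(2.0 * np.sum(p * (1 - p))))
    M = (Xd - 2 * p) / c
    n = len(y)
    G = M @ M.T
    V = G + delta * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ beta
    alpha = M.T @ np.linalg.solve(G + (delta + ridge) * np.eye(n), resid)
    return M @ alpha


def metric_suite_direct(y_true, y_pred):
    """Formula-by-formula prediction metrics with explicit sums."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    n = len(y_true)
    ybar = sum(y_true) / n
    phat = sum(y_pred) / n
    rss = sum((a - b) ** 2 for a, b in zip(y_true, y_pred))
    tss = sum((a - ybar) ** 2 for a in y_true)
    sy = math.sqrt(sum((a - ybar) ** 2 for a in y_true) / (n - 1))
    sp = math.sqrt(sum((b - phat) ** 2 for b in y_pred) / (n - 1))
    r = sum((a - ybar) * (b - phat) for a, b in zip(y_true, y_pred)) / ((n - 1) * sy * sp)
    return {
        "pearson_r": r,
        "rss": rss,
        "tss": tss,
        "r_squared": 1 - rss / tss,
        "rmse": math.sqrt(rss / n),
        "mae": sum(abs(a - b) for a, b in zip(y_true, y_pred)) / n,
    }
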