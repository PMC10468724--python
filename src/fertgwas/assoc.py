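"""Single-locus EMMAX genome scan.

Variance components are estimated once under the null model and then
held fixed across SNPs (the EMMAX approximation); each marker is tested
by generalized least squares after a one-time rotation into the GRM
eigenbasis.  The scan records the substitution effect, a two-sided
t-test p-value with residual degrees of freedom, the proportion of
phenotypic variance explained, and the Mahalanobis residual sum of
squares of each single-marker model (the GLS objective, needed later by
the posterior-probability criterion of the stepwise selector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

from .kinship import Grm, compute_grm, gower_scale
from .simdata import GenotypeMatrix
from .varcomp import VarianceComponents, emma_reml, _dummy_map

__all__ = [
    "ScanResult",
    "emmax_scan",
    "snp_pve",
    "pseudo_lambda",
    "EmmaxGWAS",
]

SCAN_COLUMNS = ["snp_id", "chromosome", "position_bp", "beta", "se", "p_value",
                "neglog10p", "pve", "mrss", "zero_variance"]


@dataclass
class ScanResult:
    """Per-SNP association records plus the shared scan context."""

    records: pd.DataFrame
    mrss_null: float
    vc: VarianceComponents
    n: int
    df_resid: int

    def __len__(self) -> int:
        return len(self.records)


def _rotate(y, X, grm, vc):
    lam, U = grm.eig()
    w = vc.sigma_g2 * lam + vc.sigma_e2
    if np.any(w <= 0):
        raise ValueError("V = sg2*K + se2*I is not positive definite")
    sw = 1.0 / np.sqrt(w)
    ys = sw * (U.T @ y)
    Xs = sw[:, None] * (U.T @ X)
    return ys, Xs, sw, U


def emmax_scan(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm,
    genotypes: GenotypeMatrix,
    vc: VarianceComponents | None = None,
    test: str = "t",
    exclude: list[str] | None = None,
) -> ScanResult:
    """Scan every SNP with GLS under fixed variance components.

    ``exclude`` names SNPs (cofactors already in X) to skip: they get no
    row in the output.  Zero-variance markers are emitted with p = 1,
    beta = 0, and ``zero_variance=True``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if vc is None:
        vc = emma_reml(y, X, grm)
    if test not in ("t", "chi2"):
        raise ValueError("test must be 't' or 'chi2'")
    n, q = X.shape

    ys, Xs, sw, U = _rotate(y, X, grm, vc)
    Qx, _ = np.linalg.qr(Xs)
    y_t = ys - Qx @ (Qx.T @ ys)
    mrss_null = float(y_t @ y_t)

    G = genotypes.imputed()
    Gs = sw[:, None] * (U.T @ G)
    G_t = Gs - Qx @ (Qx.T @ Gs)

    gg = np.einsum("ij,ij->j", G_t, G_t)
    gy = G_t.T @ y_t
    df = n - (q + 1)
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom for the scan")

    zero_var = gg <= 1e-12 * max(1.0, float(np.max(gg, initial=0.0)))
    safe_gg = np.where(zero_var, 1.0, gg)
    beta = np.where(zero_var, 0.0, gy / safe_gg)
    rss = mrss_null - beta * gy
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / safe_gg)
        tstat = np.where(se > 0, beta / se, 0.0)
    if test == "t":
        p = 2.0 * t_dist.sf(np.abs(tstat), df)
    else:
        from scipy.stats import chi2

        p = chi2.sf(tstat**2, 1)
    p = np.where(zero_var, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    mrss = np.where(zero_var, mrss_null, rss)

    maf = np.clip(genotypes.observed_maf(), 1e-12, 0.5)
    phen_var = vc.sigma_g2 + vc.sigma_e2
    pve = snp_pve(beta, maf, phen_var)

    records = pd.DataFrame(
        {
            "snp_id": genotypes.snp_map["snp_id"].to_numpy(),
            "chromosome": genotypes.snp_map["chromosome"].to_numpy(),
            "position_bp": genotypes.snp_map["position_bp"].to_numpy(),
            "beta": beta,
            "se": np.where(zero_var, np.nan, se),
            "p_value": p,
            "neglog10p": -np.log10(p),
            "pve": pve,
            "mrss": mrss,
            "zero_variance": zero_var,
        }
    )
    if exclude:
        records = records[~records["snp_id"].isin(set(exclude))].reset_index(drop=True)
    return ScanResult(records=records, mrss_null=mrss_null, vc=vc, n=n, df_resid=df)


def snp_pve(beta, maf, phenotypic_variance: float):
    """Proportion of phenotypic variance explained by one marker.

    pve = beta^2 * 2*maf*(1-maf) / phenotypic_variance, capped at 1.
    The heterozygosity term 2pq is the variance of the dosage under
    Hardy-Weinberg proportions.
    """
    if phenotypic_variance <= 0:
        raise ValueError("phenotypic_variance must be positive")
    beta = np.asarray(beta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    pve = beta**2 * 2.0 * maf * (1.0 - maf) / phenotypic_variance
    out = np.minimum(pve, 1.0)
    return float(out) if out.ndim == 0 else out


def pseudo_lambda(p_values) -> float:
    """Genomic inflation: log10(median observed P) / log10(0.5).

    0.5 is the median of the uniform null; a well-calibrated scan gives
    a value near 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    med = float(np.median(p))
    if med == 1.0:
        raise ValueError("median p-value of 1 leaves pseudo-lambda undefined")
    return float(np.log10(med) / np.log10(0.5))


class EmmaxGWAS(BaseEstimator):
    """Single-locus EMMAX scan with a scikit-learn interface.

    ``fit(X, y)`` takes the n x m dosage matrix, builds the
    Gower-centered VanRaden GRM, estimates variance components by EMMA
    REML under the null model (intercept plus ``covariate_matrix``),
    and scans all markers.  Fitted attributes: ``results_`` (per-SNP
    DataFrame), ``vc_``, ``lambda_`` (pseudo-lambda), ``mrss_null_``.
    """

    def __init__(self, covariate_matrix=None, test="t"):
        self.covariate_matrix = covariate_matrix
        self.test = test

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        gm = GenotypeMatrix(
            ids=[str(i) for i in range(n)], dosages=X, snp_map=_dummy_map(m)
        )
        grm = gower_scale(compute_grm(gm))
        design = np.ones((n, 1))
        if self.covariate_matrix is not None:
            design = np.hstack([design, np.atleast_2d(np.asarray(self.covariate_matrix, float))])
        scan = emmax_scan(y, design, grm, gm, test=self.test)
        self.grm_ = grm
        self.vc_ = scan.vc
        self.results_ = scan.records
        self.mrss_null_ = scan.mrss_null
        self.lambda_ = pseudo_lambda(scan.records["p_value"].to_numpy())
        return self
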