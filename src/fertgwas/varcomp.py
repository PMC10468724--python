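"""REML variance components by the EMMA eigendecomposition algorithm.

The mixed model is y = X b + u + e with Var(u) = sigma_g^2 K and
Var(e) = sigma_e^2 I.  The restricted likelihood is profiled down to a
one-dimensional function of the variance ratio delta = sigma_e^2 /
sigma_g^2 by rotating into the eigenbasis of the GRM projected onto the
complement of the fixed-effect space; the optimum is found on a grid of
log-spaced intervals with root refinement of the score in every
sign-change bracket.  Genomic heritability h2 = sigma_g^2 / (sigma_g^2
+ sigma_e^2); its variance comes from the delta method applied to the
inverse observed information of (sigma_g^2, sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .kinship import Grm, compute_grm, gower_scale
from .simdata import GenotypeMatrix

__all__ = ["VarianceComponents", "emma_reml", "covariate_variance_fraction", "EmmaREML"]

_SIGMA_G2_FLOOR = 1e-12


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    var_h2: float
    se_h2: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if abs(self.h2 - self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)) > 1e-12:
            raise ValueError("h2 inconsistent with variance components")
        if abs(self.se_h2**2 - self.var_h2) > 1e-12:
            raise ValueError("se_h2 inconsistent with var_h2")


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency
        _, R = np.linalg.qr(X)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(R).max()))
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]}; "
                         f"suspect columns {bad.tolist()})")


def _reml_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigenvalues of the projected GRM and rotated data for the REML likelihood."""
    n, q = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, q:]  # orthonormal basis of the complement of col(X)
    M = A.T @ K @ A
    xi, U = np.linalg.eigh(0.5 * (M + M.T))
    xi = np.maximum(xi, 0.0)
    eta = U.T @ (A.T @ y)
    return xi, eta


def _restricted_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    nq = len(xi)
    w = xi + delta
    s = float(np.sum(eta2 / w))
    return 0.5 * (nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(s) - np.sum(np.log(w)))


def _restricted_score(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    nq = len(xi)
    w = xi + delta
    s1 = float(np.sum(eta2 / w))
    s2 = float(np.sum(eta2 / w**2))
    return 0.5 * (nq * s2 / s1 - float(np.sum(1.0 / w)))


def _h2_variance(sigma_g2: float, sigma_e2: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """Delta-method variance of h2 from the observed REML information."""
    w = sigma_g2 * xi + sigma_e2
    # second derivatives of the restricted log-likelihood in (sg2, se2)
    def hess_term(fa, fb):
        return float(0.5 * np.sum(fa * fb / w**2) - np.sum(fa * fb * eta2 / w**3))

    h_aa = hess_term(xi, xi)
    h_ab = hess_term(xi, np.ones_like(xi))
    h_bb = hess_term(np.ones_like(xi), np.ones_like(xi))
    info = -np.array([[h_aa, h_ab], [h_ab, h_bb]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    tot = sigma_g2 + sigma_e2
    grad = np.array([sigma_e2, -sigma_g2]) / tot**2
    return max(float(grad @ cov @ grad), 0.0)


def emma_reml(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm,
    delta_min: float = 1e-5,
    delta_max: float = 1e5,
    grid_points: int = 100,
) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_e2) by REML over delta = sigma_e2/sigma_g2.

    The profiled restricted likelihood is evaluated on ``grid_points``
    log-spaced intervals over ``[delta_min, delta_max]``; every interval
    where the score changes sign is refined by root bracketing, and the
    global optimum among all stationary points and both endpoints is
    returned.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    _check_design(X)
    n, q = X.shape
    if n <= q + 1:
        raise ValueError("need n > rank(X) + 1 for REML")

    xi, eta = _reml_spectrum(y, X, grm.values)
    eta2 = eta**2

    grid = np.logspace(np.log10(delta_min), np.log10(delta_max), grid_points + 1)
    scores = np.array([_restricted_score(d, xi, eta2) for d in grid])
    candidates = [delta_min, delta_max]
    for i in range(grid_points):
        if np.sign(scores[i]) * np.sign(scores[i + 1]) < 0:
            root = brentq(_restricted_score, grid[i], grid[i + 1], args=(xi, eta2),
                          xtol=1e-12, rtol=8.9e-16)
            candidates.append(root)
        elif scores[i] == 0.0:
            candidates.append(grid[i])

    lls = [_restricted_loglik(d, xi, eta2) for d in candidates]
    best = int(np.argmax(lls))
    delta = float(candidates[best])
    ll = float(lls[best])

    nq = len(xi)
    sigma_g2 = max(float(np.sum(eta2 / (xi + delta)) / nq), _SIGMA_G2_FLOOR)
    sigma_e2 = delta * sigma_g2
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    var_h2 = _h2_variance(sigma_g2, sigma_e2, xi, eta2)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        h2=h2,
        var_h2=var_h2,
        se_h2=float(np.sqrt(var_h2)),
        reml_loglik=ll,
    )


def full_loglik(y: np.ndarray, X: np.ndarray, grm: Grm, vc: VarianceComponents) -> float:
    """Unrestricted Gaussian log-likelihood at the GLS fixed effects.

    Used by the stepwise model-selection criteria: the full-model
    log-likelihood l_F evaluated at the REML variance components and
    the corresponding generalized-least-squares estimate of the fixed
    effects.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lam, U = grm.eig()
    w = vc.sigma_g2 * lam + vc.sigma_e2
    sw = 1.0 / np.sqrt(w)
    ys = sw * (U.T @ y)
    Xs = sw[:, None] * (U.T @ X)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    n = len(y)
    return float(-0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(w)) + r @ r))


def covariate_variance_fraction(y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of phenotypic variance explained by fixed covariates.

    Ordinary least squares of y on X; returns 1 - RSS/TSS with TSS
    about the mean.  A constant phenotype yields 0 with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_design(X)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("constant phenotype: covariate variance fraction set to 0")
        return 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return 1.0 - rss / tss


def design_matrix(phenotypes, covariates: str = "farm_season") -> np.ndarray:
    """Intercept-plus-dummies design from a phenotype table.

    ``covariates='none'`` gives an intercept-only design;
    ``'farm_season'`` adds treatment-coded farm and season indicators.
    """
    n = len(phenotypes)
    cols = [np.ones(n)]
    if covariates == "farm_season":
        for col in ("farm", "season"):
            levels = sorted(phenotypes[col].unique())
            for lev in levels[1:]:
                cols.append((phenotypes[col] == lev).to_numpy(dtype=float))
    elif covariates != "none":
        raise ValueError("covariates must be 'none' or 'farm_season'")
    return np.column_stack(cols)


class EmmaREML(BaseEstimator):
    """Genomic-heritability estimator with a scikit-learn interface.

    ``fit(X, y)`` takes the n x m SNP dosage matrix as features, builds
    the VanRaden GRM (Gower-centered), and runs EMMA REML with an
    optional fixed-effect covariate matrix.
    """

    def __init__(self, covariate_matrix=None, delta_min=1e-5, delta_max=1e5, grid_points=100):
        self.covariate_matrix = covariate_matrix
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.grid_points = grid_points

    def _design(self, n: int) -> np.ndarray:
        ones = np.ones((n, 1))
        if self.covariate_matrix is None:
            return ones
        C = np.atleast_2d(np.asarray(self.covariate_matrix, dtype=float))
        return np.hstack([ones, C])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        gm = GenotypeMatrix(
            ids=[str(i) for i in range(X.shape[0])],
            dosages=X,
            snp_map=_dummy_map(X.shape[1]),
        )
        grm = gower_scale(compute_grm(gm))
        design = self._design(X.shape[0])
        vc = emma_reml(y, design, grm, self.delta_min, self.delta_max, self.grid_points)
        self.grm_ = grm
        self.vc_ = vc
        self.sigma_g2_ = vc.sigma_g2
        self.sigma_e2_ = vc.sigma_e2
        self.delta_ = vc.delta
        self.h2_ = vc.h2
        self.var_h2_ = vc.var_h2
        self.se_h2_ = vc.se_h2
        self.reml_loglik_ = vc.reml_loglik
        return self


def _dummy_map(m: int):
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(m)],
            "chromosome": 1,
            "position_bp": np.arange(1, m + 1),
            "allele_minor": "A",
            "allele_major": "G",
            "maf": 0.5,
        }
    )
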