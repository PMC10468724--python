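"""GBLUP genomic prediction and k-fold cross-validation.

The model is y = X_f B_f + u + e with Var(u) = sigma_g^2 G (a genomic
relationship matrix) and Var(e) = sigma_e^2 I.  Variance components come
from EMMA REML, fixed effects from GLS, and the genomic breeding values
from the BLUP u_hat = sigma_g^2 G V^{-1} (y - X B_f).  Allele
substitution effects are recovered through the overall-normalized
genotype matrix M (columns centered at 2p_j, one global scale constant
sqrt(2 sum p_j (1-p_j)) so that M M' equals the VanRaden GRM); u = M a.

Cross-validation follows the masked-phenotype design: the GRM is built
once from all samples, each fold's model is trained on the complement
with validation phenotypes withheld, and validation phenotypes are
predicted as X_fv B_f + u_v where u_v uses the genomic relationships
between validation and training individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .kinship import Grm, compute_grm, gower_scale
from .simdata import GenotypeMatrix
from .varcomp import VarianceComponents, emma_reml, _dummy_map

__all__ = [
    "GblupFit",
    "MetricSet",
    "CvSummary",
    "normalized_genotypes",
    "fit_gblup",
    "predict_fold",
    "cross_validate",
    "prediction_metrics",
    "accuracy_from_ability",
    "GBLUP",
]

METRIC_NAMES = ("pearson_r", "rss", "tss", "r_squared", "rmse", "mae")


@dataclass
class MetricSet:
    pearson_r: float
    rss: float
    tss: float
    r_squared: float
    rmse: float
    mae: float

    def __post_init__(self) -> None:
        if abs(self.r_squared - (1.0 - self.rss / self.tss)) > 1e-12:
            raise ValueError("r_squared inconsistent with rss/tss")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass
class GblupFit:
    fixed_effects: np.ndarray
    gebv: np.ndarray
    ase: np.ndarray
    vc: VarianceComponents
    allele_freq: np.ndarray = field(repr=False, default=None)
    norm_const: float = 1.0


@dataclass
class CvSummary:
    k: int
    iterations: int
    folds: pd.DataFrame  # one row per fold per iteration
    means: dict[str, float]
    sds: dict[str, float]
    predictive_ability_mean: float
    predictive_ability_sd: float
    prediction_accuracy_mean: float
    prediction_accuracy_sd: float
    h2_whole_data: float
    seed: int


def normalized_genotypes(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Overall-normalized dosage matrix M with M M' = VanRaden G.

    Returns (M, allele frequencies p, normalization constant c) where
    M = (X - 2p) / c and c = sqrt(2 sum_j p_j (1 - p_j)) over
    polymorphic markers (monomorphic columns are zero after centering).
    """
    X = genotypes.imputed()
    p = X.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    c = float(np.sqrt(het.sum()))
    if c == 0:
        raise ValueError("all markers monomorphic; normalization undefined")
    M = (X - 2.0 * p) / c
    return M, p, c


def fit_gblup(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm,
    genotypes: GenotypeMatrix | None = None,
    vc: VarianceComponents | None = None,
    ridge: float = 1e-8,
) -> GblupFit:
    """Fit the GBLUP model and recover marker effects.

    ``ridge`` stabilizes the inverse of M M' when back-solving the
    allele substitution effects; it is added to the diagonal only there,
    never to the mixed-model V.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if vc is None:
        vc = emma_reml(y, X, grm)

    lam, U = grm.eig()
    w = vc.sigma_g2 * lam + vc.sigma_e2
    if np.any(w <= 0):
        raise ValueError("V is singular; consider a ridge on the GRM diagonal")
    sw = 1.0 / np.sqrt(w)
    ys = sw * (U.T @ y)
    Xs = sw[:, None] * (U.T @ X)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = y - X @ beta
    v_inv_resid = U @ ((U.T @ resid) / w)
    gebv = vc.sigma_g2 * (grm.values @ v_inv_resid)

    ase = np.array([])
    p = None
    c = 1.0
    if genotypes is not None:
        M, p, c = normalized_genotypes(genotypes)
        K = M @ M.T
        K[np.diag_indices_from(K)] += ridge
        ase = M.T @ np.linalg.solve(K, gebv)
    return GblupFit(fixed_effects=beta, gebv=gebv, ase=ase, vc=vc, allele_freq=p, norm_const=c)


def prediction_metrics(y_true, y_pred) -> MetricSet:
    """The six summary statistics used to judge predicted phenotypes.

    Pearson correlation (sample, n-1 denominators), RSS, TSS about the
    observed mean, R^2 = 1 - RSS/TSS, RMSE = sqrt(RSS/n), and MAE.  A
    constant truth vector is an error (TSS = 0); a constant prediction
    leaves the correlation undefined (NaN, with a warning).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and prediction")
    n = len(y_true)
    if n < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("constant y_true: TSS is zero, metrics undefined")
    rss = float(np.sum((y_true - y_pred) ** 2))
    if np.std(y_pred) == 0.0:
        warnings.warn("constant prediction: Pearson correlation undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return MetricSet(
        pearson_r=r,
        rss=rss,
        tss=tss,
        r_squared=1.0 - rss / tss,
        rmse=float(np.sqrt(rss / n)),
        mae=float(np.mean(np.abs(y_true - y_pred))),
    )


def accuracy_from_ability(predictive_ability: float, h2: float) -> float:
    """Prediction accuracy: predictive ability / sqrt(h2)."""
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    return predictive_ability / np.sqrt(h2)


def predict_fold(y, X, grm: Grm, t_idx, v_idx):
    """Train on ``t_idx`` and predict the ``v_idx`` phenotypes.

    Only ``y[t_idx]`` is ever read: validation phenotypes are masked by
    construction.  Returns (y_hat_v, u_hat_v, beta).
    """
    t_idx = np.asarray(t_idx)
    v_idx = np.asarray(v_idx)
    grm_t = grm.subset(t_idx)
    vc = emma_reml(y[t_idx], X[t_idx], grm_t)
    lam, U = grm_t.eig()
    w = vc.sigma_g2 * lam + vc.sigma_e2
    sw = 1.0 / np.sqrt(w)
    ys = sw * (U.T @ y[t_idx])
    Xs = sw[:, None] * (U.T @ X[t_idx])
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = y[t_idx] - X[t_idx] @ beta
    v_inv_resid = U @ ((U.T @ resid) / w)
    u_v = vc.sigma_g2 * (grm.values[np.ix_(v_idx, t_idx)] @ v_inv_resid)
    return X[v_idx] @ beta + u_v, u_v, beta


def cross_validate(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm,
    genotypes: GenotypeMatrix | None = None,
    k: int = 3,
    iterations: int = 10,
    seed: int = 0,
) -> CvSummary:
    """Random-sampling k-fold cross-validation of GBLUP predictions.

    Per iteration the samples are randomly partitioned into k folds of
    near-equal size.  Each fold serves once as validation: the model is
    trained on the complement (validation phenotypes are never seen),
    and the fold's phenotypes are predicted from the trained fixed
    effects and the genomic relationships to the training individuals.
    Predictive ability is the correlation of the predicted breeding
    values with the observed validation phenotypes; prediction accuracy
    divides its mean by sqrt(h2) from a whole-data fit with the same
    fixed-effect specification.  Means and SDs are taken over all
    k * iterations fold-level values.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError("need at least 2k samples")

    rng = np.random.default_rng(seed)
    vc_full = emma_reml(y, X, grm)
    h2_full = vc_full.h2

    rows = []
    for it in range(iterations):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for f, v_idx in enumerate(folds):
            if len(v_idx) < 3:
                raise ValueError("validation fold smaller than 3 samples")
            v_idx = np.sort(v_idx)
            t_idx = np.sort(np.setdiff1d(perm, v_idx))
            y_hat, u_v, _ = predict_fold(y, X, grm, t_idx, v_idx)
            ms = prediction_metrics(y[v_idx], y_hat)
            ability = float(np.corrcoef(u_v, y[v_idx])[0, 1]) if np.std(u_v) > 0 else float("nan")
            rows.append(
                {"iteration": it, "fold": f, "n_validation": len(v_idx),
                 "predictive_ability": ability, **ms.as_dict()}
            )

    folds_df = pd.DataFrame(rows)
    value_cols = ["predictive_ability", *METRIC_NAMES]
    means = {c: float(folds_df[c].mean()) for c in value_cols}
    sds = {c: float(folds_df[c].std(ddof=1)) for c in value_cols}
    ability_mean = means["predictive_ability"]
    ability_sd = sds["predictive_ability"]
    return CvSummary(
        k=k,
        iterations=iterations,
        folds=folds_df,
        means=means,
        sds=sds,
        predictive_ability_mean=ability_mean,
        predictive_ability_sd=ability_sd,
        prediction_accuracy_mean=accuracy_from_ability(ability_mean, h2_full),
        prediction_accuracy_sd=ability_sd / float(np.sqrt(h2_full)),
        h2_whole_data=h2_full,
        seed=seed,
    )


class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP with a scikit-learn fit/predict interface.

    ``fit(X, y)`` takes the n x m dosage matrix, builds the VanRaden
    GRM (Gower-centered by default), estimates variance components and
    breeding values, and back-solves allele substitution effects.
    ``predict(X_new)`` applies the training normalization to new
    dosages and returns fixed-effect predictions plus M_new @ ase.
    """

    def __init__(self, covariate_matrix=None, grm_scaling="gower", ridge=1e-8):
        self.covariate_matrix = covariate_matrix
        self.grm_scaling = grm_scaling
        self.ridge = ridge

    def _design(self, n):
        ones = np.ones((n, 1))
        if self.covariate_matrix is None:
            return ones
        return np.hstack([ones, np.atleast_2d(np.asarray(self.covariate_matrix, float))])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        gm = GenotypeMatrix(ids=[str(i) for i in range(n)], dosages=X, snp_map=_dummy_map(m))
        grm = compute_grm(gm)
        if self.grm_scaling == "gower":
            grm = gower_scale(grm)
        elif self.grm_scaling != "raw":
            raise ValueError("grm_scaling must be 'gower' or 'raw'")
        design = self._design(n)
        fit = fit_gblup(y, design, grm, genotypes=gm, ridge=self.ridge)
        self.fit_ = fit
        self.grm_ = grm
        self.vc_ = fit.vc
        self.h2_ = fit.vc.h2
        self.beta_ = fit.fixed_effects
        self.gebv_ = fit.gebv
        self.ase_ = fit.ase
        self.allele_freq_ = fit.allele_freq
        self.norm_const_ = fit.norm_const
        return self

    def predict(self, X, covariate_matrix=None):
        X = np.asarray(X, dtype=float)
        M = (X - 2.0 * self.allele_freq_) / self.norm_const_
        design = np.ones((X.shape[0], 1))
        if covariate_matrix is not None:
            design = np.hstack([design, np.atleast_2d(np.asarray(covariate_matrix, float))])
        fixed = design @ self.beta_[: design.shape[1]]
        return fixed + M @ self.ase_
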