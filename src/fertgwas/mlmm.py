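"""Multi-locus EMMAX: stepwise cofactor selection with optimality criteria.

Forward inclusion adds the most significant SNP of each scan to the
fixed effects ("cofactor") for a fixed number of steps; backward
elimination then removes the least significant cofactor per step until
one remains.  Variance components are re-estimated from scratch at
every step with the current cofactors in the design, and each step
records a full-genome scan (cofactors excluded) plus six
model-optimality criteria:

* BIC  = -2 l_F + p log n, with l_F the full-model log-likelihood,
  p counting the intercept, the variance ratio delta, every additional
  fixed covariate and every cofactor;
* EBIC = BIC + 2 log C(n, p - q), q being the cofactor-free parameter
  count (the combinatorial term prices the model search space);
* MBIC = BIC + 2 p log(m / 2.2 - 1), m the markers tested this step;
* Bonferroni (forward only): the best p-value of the preceding scan is
  below 1 / (20 m);
* Multiple Bonferroni: every cofactor's drop-one re-test p-value is
  below 1 / (20 m);
* MPPA: every cofactor's posterior probability of association is at
  least 0.5, with Bayes factors built from Mahalanobis residual sums
  of squares and a prior of 1/m per marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .assoc import ScanResult, emmax_scan, _rotate
from .kinship import Grm, compute_grm, gower_scale
from .simdata import GenotypeMatrix
from .varcomp import emma_reml, full_loglik, _dummy_map

__all__ = [
    "CriteriaRecord",
    "StepwisePath",
    "run_mlmm",
    "evaluate_criteria",
    "mppa_posterior",
    "optimal_models",
    "MLMMSelector",
]

CRITERIA = ("bic", "ebic", "mbic", "bonferroni", "mbonf", "mppa")


@dataclass
class CriteriaRecord:
    step_index: int
    direction: str  # initial | forward | backward
    cofactors: list[str]
    bic: float
    ebic: float
    mbic: float
    bonferroni_ok: bool | None  # None outside the forward phase
    mbonf_ok: bool
    mppa_min_pp: float
    h2_at_step: float
    vg_at_step: float
    ve_at_step: float
    cofactor_pvalues: dict[str, float] = field(default_factory=dict)
    cofactor_pps: dict[str, float] = field(default_factory=dict)


@dataclass
class StepwisePath:
    records: list[CriteriaRecord]
    scans: list[pd.DataFrame]

    def __post_init__(self) -> None:
        if self.records and self.records[0].cofactors:
            raise ValueError("step 0 must have zero cofactors")

    @property
    def n_steps(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "step": r.step_index,
                    "direction": r.direction,
                    "n_cofactors": len(r.cofactors),
                    "cofactors": ",".join(r.cofactors),
                    "bic": r.bic,
                    "ebic": r.ebic,
                    "mbic": r.mbic,
                    "bonferroni_ok": r.bonferroni_ok,
                    "mbonf_ok": r.mbonf_ok,
                    "mppa_min_pp": r.mppa_min_pp,
                    "h2": r.h2_at_step,
                    "vg": r.vg_at_step,
                    "ve": r.ve_at_step,
                }
            )
        return pd.DataFrame(rows)


def mppa_posterior(
    mrss_h0: float, mrss_k: float, n: int, m: int, parenthesization: str = "standard"
) -> float:
    """Posterior probability of association for one marker.

    bf = exp((n log(mrss_h0/mrss_k) - log n) / 2) is the
    BIC-approximation Bayes factor for one added parameter; the prior
    is pr = 1/m, posterior odds po = bf * pr / (1 - pr), and
    pp = po / (1 + po).  ``parenthesization='outer'`` selects the
    alternative reading exp(n log(mrss_h0/mrss_k) - log(n)/2).
    Computed in log space so extreme Bayes factors do not overflow.
    """
    if mrss_h0 <= 0 or mrss_k <= 0:
        raise ValueError("mrss values must be positive")
    if m < 2:
        raise ValueError("need m >= 2 markers for a proper prior")
    log_ratio = math.log(mrss_h0 / mrss_k)
    if parenthesization == "standard":
        log_bf = (n * log_ratio - math.log(n)) / 2.0
    elif parenthesization == "outer":
        log_bf = n * log_ratio - math.log(n) / 2.0
    else:
        raise ValueError("parenthesization must be 'standard' or 'outer'")
    log_prior_odds = math.log(1.0 / m) - math.log(1.0 - 1.0 / m)
    log_po = log_bf + log_prior_odds
    # pp = po/(1+po) = logistic(log_po)
    if log_po > 0:
        pp = 1.0 / (1.0 + math.exp(-log_po))
    else:
        e = math.exp(log_po)
        pp = e / (1.0 + e)
    return min(max(pp, np.finfo(float).tiny), 1.0 - np.finfo(float).eps)


def evaluate_criteria(
    l_f: float,
    n: int,
    p: int,
    q: int,
    m: int,
    best_prev_p: float | None,
    cofactor_pvalues: dict[str, float],
    cofactor_pps: dict[str, float],
    direction: str,
) -> dict:
    """Compute the six criteria for one fitted stepwise model.

    ``p`` counts all model parameters (intercept, delta, covariates,
    cofactors); ``q`` the cofactor-free baseline; ``m`` the markers
    tested in this step; ``best_prev_p`` the best p-value of the
    preceding scan (forward steps only).
    """
    if m <= 3:
        raise ValueError("MBIC needs m > 3 markers in the current step")
    if p < q:
        raise ValueError("p must be >= q")
    bic = -2.0 * l_f + p * math.log(n)
    k = p - q
    log_choose = float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    ebic = bic + 2.0 * log_choose
    mbic = bic + 2.0 * p * math.log(m / 2.2 - 1.0)
    threshold = 1.0 / (20.0 * m)
    bonferroni_ok = None
    if direction == "forward":
        bonferroni_ok = bool(best_prev_p is not None and best_prev_p < threshold)
    mbonf_ok = all(pv < threshold for pv in cofactor_pvalues.values())
    mppa_min_pp = min(cofactor_pps.values(), default=1.0)
    return {
        "bic": bic,
        "ebic": ebic,
        "mbic": mbic,
        "bonferroni_ok": bonferroni_ok,
        "mbonf_ok": mbonf_ok,
        "mppa_min_pp": mppa_min_pp,
    }


def _cofactor_tests(y, X_base, grm, genotypes, cofactors, vc, m_step):
    """Drop-one re-test of every cofactor in the current model.

    For cofactor c the base design is [covariates, other cofactors];
    its p-value comes from GLS of y on base plus c under the current
    variance components, and its posterior probability from the
    Mahalanobis RSS of the base model (without c) versus the full
    model (all cofactors).
    """
    from scipy.stats import t as t_dist

    dos = genotypes.imputed()
    id_to_col = {sid: j for j, sid in enumerate(genotypes.snp_map["snp_id"])}
    n = len(y)
    pvals: dict[str, float] = {}
    pps: dict[str, float] = {}

    cof_cols = {c: dos[:, id_to_col[c]] for c in cofactors}
    X_full = np.column_stack([X_base] + [cof_cols[c] for c in cofactors])
    ys, Xs_full, sw, U = _rotate(y, X_full, grm, vc)
    Qf, _ = np.linalg.qr(Xs_full)
    r_full = ys - Qf @ (Qf.T @ ys)
    mrss_full = float(r_full @ r_full)

    for c in cofactors:
        others = [o for o in cofactors if o != c]
        X_wo = np.column_stack([X_base] + [cof_cols[o] for o in others])
        Xs_wo = sw[:, None] * (U.T @ X_wo)
        Qw, _ = np.linalg.qr(Xs_wo)
        y_t = ys - Qw @ (Qw.T @ ys)
        mrss_h0 = float(y_t @ y_t)
        g = sw * (U.T @ cof_cols[c])
        g_t = g - Qw @ (Qw.T @ g)
        gg = float(g_t @ g_t)
        if gg <= 1e-12:
            pvals[c] = 1.0
            pps[c] = mppa_posterior(mrss_h0, mrss_h0, n, m_step)
            continue
        beta = float(g_t @ y_t) / gg
        rss = max(mrss_h0 - beta**2 * gg, 0.0)
        df = n - X_wo.shape[1] - 1
        se = math.sqrt(rss / df / gg)
        tstat = beta / se if se > 0 else 0.0
        pvals[c] = float(2.0 * t_dist.sf(abs(tstat), df))
        pps[c] = mppa_posterior(mrss_h0, mrss_full, n, m_step)
    return pvals, pps


def run_mlmm(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm,
    genotypes: GenotypeMatrix,
    n_forward: int = 10,
    test: str = "t",
) -> StepwisePath:
    """Forward inclusion then backward elimination of SNP cofactors.

    Returns the full path: one :class:`CriteriaRecord` and one scan per
    step (step 0 is the cofactor-free single-locus model).  Backward
    elimination runs until a single cofactor remains, giving
    ``n_forward - 1`` backward records after ``n_forward`` forward
    records.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q_cols = X.shape
    m_total = genotypes.n_snps
    if n_forward < 0:
        raise ValueError("n_forward must be >= 0")
    if n_forward >= m_total:
        raise ValueError("n_forward must be smaller than the SNP count")

    dos = genotypes.imputed()
    id_to_col = {sid: j for j, sid in enumerate(genotypes.snp_map["snp_id"])}
    q_params = q_cols + 1  # intercept+covariates plus delta

    records: list[CriteriaRecord] = []
    scans: list[pd.DataFrame] = []
    cofactors: list[str] = []
    prev_scan: ScanResult | None = None

    def fit_step(step_index: int, direction: str) -> ScanResult:
        X_step = X
        if cofactors:
            X_step = np.column_stack([X] + [dos[:, id_to_col[c]] for c in cofactors])
        vc = emma_reml(y, X_step, grm)
        scan = emmax_scan(y, X_step, grm, genotypes, vc=vc, test=test, exclude=cofactors)
        m_step = len(scan.records)
        if cofactors:
            pvals, pps = _cofactor_tests(y, X, grm, genotypes, cofactors, vc, m_step)
        else:
            pvals, pps = {}, {}
        l_f = full_loglik(y, X_step, grm, vc)
        best_prev = None
        if direction == "forward" and prev_scan is not None:
            best_prev = float(prev_scan.records["p_value"].min())
        crit = evaluate_criteria(
            l_f=l_f,
            n=n,
            p=q_params + len(cofactors),
            q=q_params,
            m=m_step,
            best_prev_p=best_prev,
            cofactor_pvalues=pvals,
            cofactor_pps=pps,
            direction=direction,
        )
        records.append(
            CriteriaRecord(
                step_index=step_index,
                direction=direction,
                cofactors=list(cofactors),
                h2_at_step=vc.h2,
                vg_at_step=vc.sigma_g2,
                ve_at_step=vc.sigma_e2,
                cofactor_pvalues=pvals,
                cofactor_pps=pps,
                **crit,
            )
        )
        scans.append(scan.records)
        return scan

    prev_scan = fit_step(0, "initial")

    for s in range(1, n_forward + 1):
        cand = prev_scan.records
        cand = cand[~cand["zero_variance"]]
        if cand.empty:
            raise ValueError("no testable SNPs left for forward selection")
        # most significant SNP; ties broken by snp_id for determinism
        best = cand.sort_values(["p_value", "snp_id"]).iloc[0]
        cofactors.append(str(best["snp_id"]))
        prev_scan = fit_step(s, "forward")

    step = n_forward
    while len(cofactors) > 1:
        rec = records[-1]
        # least significant cofactor: largest drop-one p-value
        worst = max(sorted(rec.cofactor_pvalues), key=lambda c: (rec.cofactor_pvalues[c], c))
        cofactors.remove(worst)
        step += 1
        prev_scan = fit_step(step, "backward")

    return StepwisePath(records=records, scans=scans)


def optimal_models(path: StepwisePath) -> dict[str, int]:
    """Optimal step per criterion.

    Information criteria (BIC, EBIC, MBIC) pick the minimizing step;
    the threshold criteria (Bonferroni, MBonf, MPPA) pick the step with
    the most cofactors whose condition holds.  Ties break toward fewer
    cofactors, then toward the earlier step; when nothing satisfies a
    threshold criterion the cofactor-free step 0 is returned.
    """
    out: dict[str, int] = {}
    recs = path.records

    for crit in ("bic", "ebic", "mbic"):
        best = min(recs, key=lambda r: (getattr(r, crit), len(r.cofactors), r.step_index))
        out[crit] = best.step_index

    def largest_satisfying(flag_fn) -> int:
        ok = [r for r in recs if flag_fn(r)]
        if not ok:
            return 0
        best = max(ok, key=lambda r: (len(r.cofactors), -r.step_index))
        return best.step_index

    out["bonferroni"] = largest_satisfying(lambda r: r.bonferroni_ok is True)
    out["mbonf"] = largest_satisfying(lambda r: r.mbonf_ok and r.cofactors)
    out["mppa"] = largest_satisfying(lambda r: r.cofactors and r.mppa_min_pp >= 0.5)
    return out


class MLMMSelector(BaseEstimator):
    """Stepwise multi-locus scan with a scikit-learn interface.

    ``fit(X, y)`` takes the dosage matrix, builds the Gower-centered
    GRM, and runs the forward/backward path.  Fitted attributes:
    ``path_``, ``optimal_`` (criterion -> step index), ``selected_``
    (criterion -> cofactor list).
    """

    def __init__(self, covariate_matrix=None, n_forward=10, test="t"):
        self.covariate_matrix = covariate_matrix
        self.n_forward = n_forward
        self.test = test

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        gm = GenotypeMatrix(ids=[str(i) for i in range(n)], dosages=X, snp_map=_dummy_map(m))
        grm = gower_scale(compute_grm(gm))
        design = np.ones((n, 1))
        if self.covariate_matrix is not None:
            design = np.hstack([design, np.atleast_2d(np.asarray(self.covariate_matrix, float))])
        path = run_mlmm(y, design, grm, gm, n_forward=self.n_forward, test=self.test)
        self.path_ = path
        self.optimal_ = optimal_models(path)
        self.selected_ = {
            crit: path.records[step].cofactors for crit, step in self.optimal_.items()
        }
        return self
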