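"""Sample- and SNP-level quality control.

Filters are applied in a fixed order: samples by call rate first, then
SNPs by call rate, minor-allele frequency, and Hardy-Weinberg
equilibrium, with every SNP statistic computed on the post-sample-filter
matrix.  The HWE test is the exact conditional test computed in log
space so that p-values far below 1e-25 are resolved without underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .simdata import GenotypeMatrix

__all__ = ["QcReport", "hwe_exact_pvalue", "hwe_chi2_pvalue", "apply_qc"]


@dataclass
class QcReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    excluded_sample_call_rate: int
    excluded_snp_call_rate: int
    excluded_maf: int
    excluded_hwe: int
    thresholds: dict

    def __post_init__(self) -> None:
        if self.n_samples_in - self.excluded_sample_call_rate != self.n_samples_out:
            raise ValueError("sample exclusion counts do not reconcile")
        snp_excl = self.excluded_snp_call_rate + self.excluded_maf + self.excluded_hwe
        if self.n_snps_in - snp_excl != self.n_snps_out:
            raise ValueError("SNP exclusion counts do not reconcile")

    def to_dict(self) -> dict:
        return asdict(self)


def _hwe_log_probs(n_minor_alleles: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every admissible heterozygote count.

    Conditional on the minor-allele count ``n_a`` among ``2n`` alleles,
    the heterozygote count ranges over values with the parity of ``n_a``
    up to ``min(n_a, 2n - n_a)``.  Probabilities follow the exact
    conditional distribution
    ``P(het) = n! / (n_AA! n_Aa! n_aa!) * 2^het * n_a! n_b! / (2n)!``.
    """
    n_a = n_minor_alleles
    n_b = 2 * n_total - n_a
    hets = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    hom_minor = (n_a - hets) // 2
    hom_major = n_total - hets - hom_minor
    logp = (
        gammaln(n_total + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n_total + 1)
    )
    logp -= logsumexp(logp)  # exact normalization, guards accumulated rounding
    return hets, logp


def hwe_exact_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional HWE test p-value (no mid-p correction).

    Sums the probabilities of all heterozygote counts no more probable
    than the observed one, given the allele counts.  Computed in log
    space; extremely small p-values (far below 1e-25) are exact to
    floating-point precision rather than flushed to zero.
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n_total = sum(counts)
    if n_total == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_hom_minor + n_het
    hets, logp = _hwe_log_probs(n_a, n_total)
    obs_logp = logp[hets == n_het][0]
    keep = logp <= obs_logp + 1e-10  # tolerance for ties in probability
    p = float(np.exp(logsumexp(logp[keep])))
    return min(p, 1.0)


def hwe_log10_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """log10 of the exact HWE p-value, safe for p far below 1e-300."""
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n_total = sum(counts)
    if n_total == 0:
        raise ValueError("at least one genotype count must be positive")
    n_a = 2 * n_hom_minor + n_het
    hets, logp = _hwe_log_probs(n_a, n_total)
    obs_logp = logp[hets == n_het][0]
    keep = logp <= obs_logp + 1e-10
    return float(logsumexp(logp[keep]) / np.log(10.0))


def hwe_chi2_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    counts = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    if np.any(expected == 0):
        return 1.0
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[~np.isnan(col)]
    return int(np.sum(obs == 2)), int(np.sum(obs == 1)), int(np.sum(obs == 0))


def apply_qc(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame | None = None,
    sample_call_rate_min: float = 0.90,
    snp_missing_max: float = 0.15,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-25,
    hwe_test: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame | None, QcReport]:
    """Filter samples then SNPs, in a fixed order with strict boundaries.

    Exclusions are strict: a sample is removed iff its call rate is
    below ``sample_call_rate_min``; a SNP iff its missing fraction
    exceeds ``snp_missing_max``, its MAF (from non-missing calls) is
    below ``maf_min``, or its HWE p-value is below ``hwe_p_min``.  SNP
    statistics are computed after sample removal; a SNP failing several
    rules is attributed to the first in the order call rate, MAF, HWE.
    """
    if hwe_test not in ("exact", "chi2"):
        raise ValueError("hwe_test must be 'exact' or 'chi2'")
    n_in, m_in = genotypes.n_individuals, genotypes.n_snps

    call_rate = 1.0 - np.isnan(genotypes.dosages).mean(axis=1)
    keep_samples = np.flatnonzero(call_rate >= sample_call_rate_min)
    n_sample_excl = n_in - len(keep_samples)
    if len(keep_samples) == 0:
        raise ValueError("sample call-rate filter removed every sample")

    gm = genotypes.subset(sample_idx=keep_samples)
    dos = gm.dosages

    miss = np.isnan(dos).mean(axis=0)
    fail_call = miss > snp_missing_max

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = (maf < maf_min) | np.isnan(maf)

    # log-space threshold comparison keeps the extreme tail exact
    log10_thresh = np.log10(hwe_p_min) if hwe_p_min > 0 else -np.inf
    fail_hwe = np.zeros(gm.n_snps, dtype=bool)
    pending = ~(fail_call | fail_maf)
    for j in np.flatnonzero(pending):
        hom_minor, het, hom_major = _genotype_counts(dos[:, j])
        if hom_minor + het + hom_major == 0:
            continue
        if hwe_test == "exact":
            fail_hwe[j] = hwe_log10_pvalue(hom_minor, het, hom_major) < log10_thresh
        else:
            fail_hwe[j] = hwe_chi2_pvalue(hom_minor, het, hom_major) < hwe_p_min

    n_fail_call = int(fail_call.sum())
    n_fail_maf = int((fail_maf & ~fail_call).sum())
    n_fail_hwe = int(fail_hwe.sum())
    keep_snps = np.flatnonzero(~(fail_call | fail_maf | fail_hwe))
    if len(keep_snps) == 0:
        responsible = max(
            [("snp_call_rate", n_fail_call), ("maf", n_fail_maf), ("hwe", n_fail_hwe)],
            key=lambda kv: kv[1],
        )[0]
        raise ValueError(f"SNP filters removed every SNP (dominant rule: {responsible})")

    gm = gm.subset(snp_idx=keep_snps)
    report = QcReport(
        n_samples_in=n_in,
        n_samples_out=gm.n_individuals,
        n_snps_in=m_in,
        n_snps_out=gm.n_snps,
        excluded_sample_call_rate=n_sample_excl,
        excluded_snp_call_rate=n_fail_call,
        excluded_maf=n_fail_maf,
        excluded_hwe=n_fail_hwe,
        thresholds={
            "sample_call_rate_min": sample_call_rate_min,
            "snp_missing_max": snp_missing_max,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "hwe_test": hwe_test,
        },
    )

    phen_out = None
    if phenotypes is not None:
        phen_out = phenotypes[phenotypes["iid"].isin(gm.ids)].reset_index(drop=True)
    return gm, phen_out, report
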