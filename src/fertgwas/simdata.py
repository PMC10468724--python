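"""Synthetic genotype and phenotype generation with known ground truth.

The generator emulates a herd-structured dairy study design: a dense
biallelic SNP panel with block LD, a continuous probability-index
phenotype in [0, 1] built as a logistic transform of a liability that
combines farm/season fixed effects, a handful of planted QTL, a
polygenic term, and residual noise, plus within-stratum selection of
the phenotypic tails.  Every downstream stage (QC, kinship, variance
components, association, prediction) can therefore be tested against
recorded truth without any external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "TrueParams",
    "simulate_genotypes",
    "simulate_study",
    "tail_select",
    "write_phenotypes",
]

SNP_MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_minor", "allele_major", "maf"]


@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with its SNP map.

    ``dosages`` is a float array with entries in {0, 1, 2} and ``nan``
    for missing calls; each entry counts copies of the minor allele.
    ``snp_map`` is a DataFrame with columns ``snp_id, chromosome,
    position_bp, allele_minor, allele_major, maf`` where ``maf`` is the
    simulation target (or estimated) minor-allele frequency.
    """

    ids: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n == 0 or m == 0:
            raise ValueError("genotype matrix must be non-empty")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} genotype rows")
        if len(self.snp_map) != m:
            raise ValueError(f"snp_map has {len(self.snp_map)} rows for {m} SNPs")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (nan)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def observed_maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean."""
        out = self.dosages.copy()
        means = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[1]]
        return out

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_individuals) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in sample_idx],
            dosages=self.dosages[np.ix_(sample_idx, snp_idx)],
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
        )


@dataclass
class TrueParams:
    """Ground truth recorded by :func:`simulate_study` for recovery tests."""

    causal_snp_ids: list[str]
    causal_effects: dict[str, float]
    h2_target: float
    realized_h2: float
    covariate_effects: dict[str, float]
    seed: int
    liability: np.ndarray = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "causal_snp_ids": self.causal_snp_ids,
            "causal_effects": self.causal_effects,
            "h2_target": self.h2_target,
            "realized_h2": self.realized_h2,
            "covariate_effects": self.covariate_effects,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_block_size: int = 10,
    ld_decay: float = 0.1,
    missing_rate: float = 0.0,
    n_chromosomes: int = 5,
    spacing_bp: int = 25_000,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a biallelic SNP panel with block LD.

    Haplotypes are simulated per LD block: all SNPs in a block share one
    target MAF drawn uniformly from ``[maf_low, maf_high]``; the first
    SNP's alleles are Bernoulli(maf) and each subsequent SNP copies the
    previous SNP's allele with probability ``1 - ld_decay``, otherwise
    redraws Bernoulli(maf).  The copy-with-mutation scheme keeps the
    marginal allele frequency at the block target while giving adjacent
    SNPs a haplotype correlation of ``1 - ld_decay``.  Genotypes are the
    sum of two independent haplotypes (HWE within blocks); missing calls
    are injected uniformly at random.

    Blocks never span chromosome boundaries; positions are 1-based and
    regularly spaced ``spacing_bp`` apart within each chromosome.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not (0.0 <= ld_decay <= 1.0):
        raise ValueError("ld_decay must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n, m = n_individuals, n_snps

    # chromosome labels and positions
    per_chrom = int(np.ceil(m / n_chromosomes))
    chroms = np.repeat(np.arange(1, n_chromosomes + 1), per_chrom)[:m]
    pos = np.concatenate(
        [spacing_bp * (np.arange(np.sum(chroms == c)) + 1) for c in np.unique(chroms)]
    )

    hap1 = np.empty((n, m), dtype=np.int8)
    hap2 = np.empty((n, m), dtype=np.int8)
    maf = np.empty(m)
    copy_p = 1.0 - ld_decay

    start = 0
    while start < m:
        chrom = chroms[start]
        stop = min(start + ld_block_size, m)
        # truncate block at chromosome boundary
        while stop > start + 1 and chroms[stop - 1] != chrom:
            stop -= 1
        p = rng.uniform(maf_low, maf_high)
        maf[start:stop] = p
        for h in (hap1, hap2):
            h[:, start] = rng.random(n) < p
            for j in range(start + 1, stop):
                fresh = rng.random(n) < p
                keep = rng.random(n) < copy_p
                h[:, j] = np.where(keep, h[:, j - 1], fresh)
        start = stop

    dosages = (hap1 + hap2).astype(float)
    if missing_rate > 0:
        mask = rng.random((n, m)) < missing_rate
        dosages[mask] = np.nan

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chroms, pos)],
            "chromosome": chroms.astype(int),
            "position_bp": pos.astype(int),
            "allele_minor": "A",
            "allele_major": "G",
            "maf": maf,
        }
    )
    ids = [f"ind{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids=ids, dosages=dosages, snp_map=snp_map)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_study(
    genotypes: GenotypeMatrix,
    n_qtl: int = 3,
    qtl_pve_each: float = 0.02,
    h2_target: float = 0.25,
    n_farms: int = 16,
    n_seasons: int = 4,
    covariate_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueParams]:
    """Generate an index phenotype over given genotypes with known truth.

    The liability is ``farm + season + QTL + polygenic + residual``.
    The genetic part (QTL + polygenic) is scaled to a fraction
    ``h2_target`` of the liability variance net of fixed effects; each
    planted QTL explains ``qtl_pve_each`` of that variance.  The full
    liability is standardized to unit variance and mapped through the
    logistic function, yielding an index in (0, 1) akin to a predicted
    probability of pregnancy.

    Returns the phenotype table (columns ``iid, ri, farm, season``) and
    a :class:`TrueParams` with the planted effects, realized
    heritability of the liability, and the seed.
    """
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    if not (0.0 <= h2_target <= 0.99):
        raise ValueError("h2_target must lie in [0, 0.99]")
    if n_qtl * qtl_pve_each > h2_target + 1e-12:
        raise ValueError(
            f"total QTL variance {n_qtl * qtl_pve_each:.4f} exceeds h2_target {h2_target:.4f}"
        )

    rng = np.random.default_rng(seed)
    n, m = genotypes.n_individuals, genotypes.n_snps
    X = genotypes.imputed()
    Xc = X - X.mean(axis=0)

    farms = rng.integers(0, n_farms, size=n)
    seasons = rng.integers(0, n_seasons, size=n)
    farm_eff = rng.normal(0.0, covariate_sd, size=n_farms)
    season_eff = rng.normal(0.0, covariate_sd, size=n_seasons)
    fixed = farm_eff[farms] + season_eff[seasons]
    fixed -= fixed.mean()

    causal_ids: list[str] = []
    effects: dict[str, float] = {}
    qtl_part = np.zeros(n)
    causal_idx = np.array([], dtype=int)
    if h2_target > 0 and n_qtl > 0:
        maf_obs = genotypes.observed_maf()
        candidates = np.flatnonzero((maf_obs >= 0.1) & (maf_obs <= 0.5))
        if len(candidates) < n_qtl:
            candidates = np.arange(m)
        # spread causal loci across the panel: even quantiles of candidates
        picks = np.unique(
            candidates[np.linspace(0, len(candidates) - 1, n_qtl).round().astype(int)]
        )
        causal_idx = picks
        betas = np.empty(len(picks))
        for i, j in enumerate(picks):
            sd_j = Xc[:, j].std()
            if sd_j == 0:
                sd_j = 1.0
            betas[i] = np.sqrt(qtl_pve_each) / sd_j * rng.choice([-1.0, 1.0])
        qtl_part = Xc[:, picks] @ betas
        causal_ids = genotypes.snp_map["snp_id"].iloc[picks].tolist()
        effects = dict(zip(causal_ids, betas))

    poly_var = h2_target - n_qtl * qtl_pve_each if h2_target > 0 else 0.0
    poly = np.zeros(n)
    if poly_var > 1e-12:
        bg = np.setdiff1d(np.arange(m), causal_idx)
        w = rng.normal(0.0, 1.0, size=len(bg))
        poly = Xc[:, bg] @ w
        poly -= poly.mean()
        sd = poly.std()
        poly = poly / sd * np.sqrt(poly_var) if sd > 0 else poly

    genetic = qtl_part + poly
    genetic -= genetic.mean()
    if h2_target > 0 and genetic.std() > 0:
        # pin the genetic variance fraction: rescale to exactly h2_target
        scale = np.sqrt(h2_target) / genetic.std()
        genetic *= scale
        effects = {k: v * scale for k, v in effects.items()}
    else:
        genetic = np.zeros(n)
        effects = {}
        causal_ids = []

    resid = rng.normal(0.0, 1.0, size=n)
    resid -= resid.mean()
    if genetic.std() > 0:
        # orthogonalize residual against the genetic component so the
        # realized variance fraction is controlled, not just expected
        resid -= genetic * (resid @ genetic) / (genetic @ genetic)
    resid = resid / resid.std() * np.sqrt(1.0 - h2_target)

    liability = fixed + genetic + resid
    total_sd = liability.std()
    liability_std = (liability - liability.mean()) / total_sd
    ri = _logistic(liability_std)

    rand_var = genetic.var() + resid.var()
    realized_h2 = float(genetic.var() / rand_var) if rand_var > 0 else 0.0

    phen = pd.DataFrame(
        {
            "iid": genotypes.ids,
            "ri": ri,
            "farm": [f"farm{f}" for f in farms],
            "season": [f"s{s}" for s in seasons],
        }
    )
    truth = TrueParams(
        causal_snp_ids=causal_ids,
        causal_effects={k: v / total_sd for k, v in effects.items()},
        h2_target=h2_target,
        realized_h2=realized_h2,
        covariate_effects={
            **{f"farm{i}": float(e) for i, e in enumerate(farm_eff)},
            **{f"s{i}": float(e) for i, e in enumerate(season_eff)},
        },
        seed=seed,
        liability=liability_std,
    )
    return phen, truth


def tail_select(
    phenotypes: pd.DataFrame,
    high_fraction: float = 0.15,
    low_fraction: float = 0.0725,
) -> pd.DataFrame:
    """Retain the phenotypic tails within every farm x season cell.

    In each cell the top ``floor(high_fraction * cell_n)`` individuals by
    index value are labeled ``high`` and the bottom
    ``floor(low_fraction * cell_n)`` are labeled ``low``; everyone else
    is dropped.  Ties are broken by individual id so the selection is
    deterministic.  Cells from which nothing is retained are skipped
    with a logged warning.
    """
    if not (0.0 <= high_fraction <= 1.0 and 0.0 <= low_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if high_fraction + low_fraction > 1.0:
        raise ValueError("high_fraction + low_fraction must be <= 1")

    pieces = []
    for (farm, season), cell in phenotypes.groupby(["farm", "season"], sort=True):
        cell = cell.sort_values(["ri", "iid"], ascending=[False, True])
        n_cell = len(cell)
        n_high = int(np.floor(high_fraction * n_cell))
        n_low = int(np.floor(low_fraction * n_cell))
        if n_high + n_low == 0:
            logger.warning("tail_select: cell (%s, %s) of size %d retains nothing", farm, season, n_cell)
            continue
        high = cell.iloc[:n_high].copy()
        high["group"] = "high"
        low = cell.iloc[n_cell - n_low:].copy()
        low["group"] = "low"
        pieces.append(high)
        pieces.append(low)
    if not pieces:
        out = phenotypes.iloc[0:0].copy()
        out["group"] = pd.Series(dtype=str)
        return out
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values("iid", kind="stable").reset_index(drop=True)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    cols = ["iid", "ri", "farm", "season"] + (["group"] if "group" in phenotypes else [])
    phenotypes.to_csv(path, index=False, columns=cols)
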