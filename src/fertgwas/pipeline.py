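"""End-to-end pipeline: QC -> GRM -> variance components -> single-locus
scan -> multi-locus stepwise -> QTL calling -> GBLUP cross-validation.

Every stage writes a diff-friendly artifact (TSV tables, JSON reports)
into the output directory; all seeds and parameters are echoed to
``run_config.json`` so a rerun reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import emmax_scan, pseudo_lambda
from .gblup import cross_validate
from .kinship import compute_grm, gower_scale
from .mlmm import optimal_models, run_mlmm
from .plinkio import align_samples, read_phenotypes, read_plink
from .qc import apply_qc
from .qtl import call_qtl, qtl_table
from .varcomp import covariate_variance_fraction, design_matrix, emma_reml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    bed_prefix: str
    pheno_path: str
    out_dir: str
    sample_call_rate_min: float = 0.90
    snp_missing_max: float = 0.15
    maf_min: float = 0.01
    hwe_p_min: float = 1e-25
    covariates: str = "farm_season"  # or "none"
    mlmm_steps: int = 10  # 0 disables the multi-locus stage
    qtl_threshold_p: float = 5e-5
    qtl_window_bp: int = 1_000_000
    cv_enabled: bool = True
    cv_k: int = 3
    cv_iterations: int = 10
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _manhattan_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready scan export with a cumulative genome coordinate."""
    out = records[["snp_id", "chromosome", "position_bp", "beta", "p_value",
                   "neglog10p", "pve"]].copy()
    offset = 0
    cum = np.empty(len(out), dtype=np.int64)
    for chrom in sorted(out["chromosome"].unique()):
        mask = (out["chromosome"] == chrom).to_numpy()
        pos = out.loc[mask, "position_bp"].to_numpy()
        cum[mask] = pos + offset
        offset += int(pos.max())
    out["genome_bp"] = cum
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every enabled stage and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "run_config.json")

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("[%s] starting", name)

    try:
        stage("input")
        genotypes = read_plink(config.bed_prefix)
        phenotypes = read_phenotypes(config.pheno_path)
        genotypes, phenotypes = align_samples(genotypes, phenotypes)

        stage("qc")
        genotypes, phenotypes, report = apply_qc(
            genotypes,
            phenotypes,
            sample_call_rate_min=config.sample_call_rate_min,
            snp_missing_max=config.snp_missing_max,
            maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min,
        )
        with open(out / "qc_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

        stage("kinship")
        grm = gower_scale(compute_grm(genotypes))

        stage("varcomp")
        y = phenotypes["ri"].to_numpy(dtype=float)
        X = design_matrix(phenotypes, config.covariates)
        vc = emma_reml(y, X, grm)
        cvf = covariate_variance_fraction(y, X) if X.shape[1] > 1 else 0.0
        _write_tsv(
            pd.DataFrame(
                [{"model": "SL-Initial", "h2": vc.h2, "var_h2": vc.var_h2,
                  "se_h2": vc.se_h2, "vg": vc.sigma_g2, "ve": vc.sigma_e2,
                  "covariate_variance_fraction": cvf}]
            ),
            out / "varcomp.tsv",
        )

        stage("assoc")
        scan = emmax_scan(y, X, grm, genotypes, vc=vc)
        _write_tsv(scan.records, out / "assoc.tsv")
        _write_tsv(_manhattan_frame(scan.records), out / "manhattan.tsv")
        lam = pseudo_lambda(scan.records["p_value"].to_numpy())
        with open(out / "inflation.json", "w") as fh:
            json.dump({"pseudo_lambda": lam}, fh, indent=2, sort_keys=True)

        stage("qtl-single")
        qtls = call_qtl(scan.records, threshold_p=config.qtl_threshold_p,
                        window_bp=config.qtl_window_bp)
        _write_tsv(qtl_table(qtls), out / "qtl_single.tsv")

        if config.mlmm_steps > 0:
            stage("mlmm")
            path = run_mlmm(y, X, grm, genotypes, n_forward=config.mlmm_steps)
            _write_tsv(path.to_frame(), out / "mlmm_path.tsv")
            optimal = optimal_models(path)
            with open(out / "mlmm_optimal.json", "w") as fh:
                json.dump(optimal, fh, indent=2, sort_keys=True)
            for step in sorted(set(optimal.values())):
                _write_tsv(path.scans[step], out / f"mlmm_scan_step{step:02d}.tsv")
                rec = path.records[step]
                ql = call_qtl(path.scans[step], threshold_p=config.qtl_threshold_p,
                              window_bp=config.qtl_window_bp, cofactors=rec.cofactors)
                _write_tsv(qtl_table(ql), out / f"qtl_mlmm_step{step:02d}.tsv")

        if config.cv_enabled:
            stage("gblup-cv")
            summary = cross_validate(
                y, X, grm, genotypes, k=config.cv_k,
                iterations=config.cv_iterations, seed=config.seed,
            )
            _write_tsv(summary.folds, out / "cv_folds.tsv")
            payload = {
                "k": summary.k,
                "iterations": summary.iterations,
                "seed": summary.seed,
                "h2_whole_data": summary.h2_whole_data,
                "means": summary.means,
                "sds": summary.sds,
                "predictive_ability_mean": summary.predictive_ability_mean,
                "predictive_ability_sd": summary.predictive_ability_sd,
                "prediction_accuracy_mean": summary.prediction_accuracy_mean,
                "prediction_accuracy_sd": summary.prediction_accuracy_sd,
            }
            with open(out / "cv_summary.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)

        with open(out / "run_log.json", "w") as fh:
            json.dump({"version": __version__, "seed": config.seed,
                       "n_samples": genotypes.n_individuals,
                       "n_snps": genotypes.n_snps}, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{current['stage']}' failed: {err}") from err
    return out
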