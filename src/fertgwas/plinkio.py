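"""PLINK bed/bim/fam and phenotype-table I/O.

The binary bed format is SNP-major: after the three magic bytes
(0x6c 0x1b 0x01) each SNP occupies ceil(n/4) bytes, two bits per
sample, least-significant pair first, with codes 00 = homozygous for
allele 1, 01 = missing, 10 = heterozygous, 11 = homozygous for allele
2.  Allele 1 in the bim file is the minor allele, so the dosage (count
of minor alleles) maps 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["write_plink", "read_plink", "read_phenotypes", "align_samples"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage; 01 is missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write a bed/bim/fam triple for a genotype matrix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.n_individuals, genotypes.n_snps

    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(m):
            buf[:] = 0
            col = genotypes.dosages[:, j]
            for i in range(n):
                v = col[i]
                code = 1 if np.isnan(v) else dosage_to_code[v]
                buf[i // 4] |= code << ((i % 4) * 2)
            fh.write(buf.tobytes())

    bim = genotypes.snp_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in bim.iterrows():
            fh.write(
                f"{row['chromosome']}\t{row['snp_id']}\t0\t{row['position_bp']}"
                f"\t{row['allele_minor']}\t{row['allele_major']}\n"
            )

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in genotypes.ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_plink(prefix) -> GenotypeMatrix:
    """Read a bed/bim/fam triple into a GenotypeMatrix.

    Dosages count copies of the bim allele-1 (minor) column.  The bed
    magic bytes and the file length implied by the fam/bim dimensions
    are both checked; a mismatch is an error rather than a silent
    misparse.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "snp_id", "cm", "position_bp",
                             "allele_minor", "allele_major"])
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} at offset 0 "
            f"(expected {_MAGIC.hex()}; not a SNP-major bed file)"
        )
    n_bytes = (n + 3) // 4
    expected = 3 + n_bytes * m
    if len(raw) != expected:
        raise ValueError(
            f"{bed_path}: file length {len(raw)} does not match the "
            f"{expected} bytes implied by {n} samples x {m} SNPs "
            f"(mismatch at offset {min(len(raw), expected)})"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    # unpack the four 2-bit codes of every byte, LSB pair first
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # n x m

    snp_map = bim[["snp_id", "chromosome", "position_bp", "allele_minor", "allele_major"]].copy()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    snp_map["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(ids=fam["iid"].tolist(), dosages=dosages,
                          snp_map=snp_map.reset_index(drop=True))


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table (CSV or TSV) with iid, ri, farm, season.

    Rows with an index value outside [0, 1] are rejected and reported
    with their row numbers; duplicate ids are an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"farm": str, "season": str})
    if "id" in df.columns and "iid" not in df.columns:
        df = df.rename(columns={"id": "iid"})
    required = {"iid", "ri", "farm", "season"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df["iid"] = df["iid"].astype(str)
    if df["iid"].duplicated().any():
        dups = df.loc[df["iid"].duplicated(), "iid"].tolist()
        raise ValueError(f"{path}: duplicate ids {dups}")
    df["ri"] = pd.to_numeric(df["ri"], errors="coerce")
    bad = df.index[df["ri"].isna() | (df["ri"] < 0) | (df["ri"] > 1)].tolist()
    if bad:
        # 1-based data rows (header is row 0)
        logger.warning("%s: rejected %d rows with ri outside [0, 1] (rows %s)",
                       path, len(bad), [i + 1 for i in bad])
        df = df.drop(index=bad).reset_index(drop=True)
    keep = ["iid", "ri", "farm", "season"] + (["group"] if "group" in df.columns else [])
    return df[keep]


def align_samples(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame):
    """Align genotypes and phenotypes on shared ids, reporting differences.

    Returns (genotypes_subset, phenotypes_subset) ordered identically.
    Ids present on only one side are dropped with a logged
    set-difference report; no overlap at all is an error.
    """
    geno_ids = set(genotypes.ids)
    phen_ids = set(phenotypes["iid"])
    only_geno = sorted(geno_ids - phen_ids)
    only_phen = sorted(phen_ids - geno_ids)
    common = geno_ids & phen_ids
    if not common:
        raise ValueError(
            f"no shared ids: {len(only_geno)} only in genotypes "
            f"(e.g. {only_geno[:5]}), {len(only_phen)} only in phenotypes "
            f"(e.g. {only_phen[:5]})"
        )
    if only_geno or only_phen:
        logger.warning(
            "sample join: dropping %d genotype-only ids %s and %d phenotype-only ids %s",
            len(only_geno), only_geno[:10], len(only_phen), only_phen[:10],
        )
    keep_idx = [i for i, iid in enumerate(genotypes.ids) if iid in common]
    gm = genotypes.subset(sample_idx=keep_idx)
    phen = phenotypes.set_index("iid").loc[gm.ids].reset_index()
    return gm, phen
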