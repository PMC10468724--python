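"""QTL calling from a genome scan.

A QTL is a cluster of at least three significant SNPs (a lead plus two
or more supporters) within a window of the lead.  Clustering is greedy
most-significant-first so it is deterministic and independent of input
row order; the window defaults to +/- 1 Mb around the lead SNP, with a
fixed 1 Mb bin alternative for the interval-based reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Qtl", "call_qtl", "qtl_table"]


@dataclass
class Qtl:
    chromosome: int
    label: str  # "chr_Mb", lead position rounded to the nearest Mb
    lead_snp_id: str
    lead_neglog10p: float
    lead_beta: float
    pve: float
    supporting_snp_count: int
    member_snp_ids: list[str]

    def __post_init__(self) -> None:
        if self.supporting_snp_count < 2:
            raise ValueError("a QTL needs at least two supporting SNPs")


def _label(chrom: int, pos_bp: int) -> str:
    mb = int(round(pos_bp / 1e6))
    return f"{int(chrom)}_{mb:02d}"


def call_qtl(
    records: pd.DataFrame,
    threshold_p: float = 5e-5,
    window_bp: int = 1_000_000,
    cofactors: list[str] | None = None,
    window_mode: str = "lead",
) -> list[Qtl]:
    """Cluster significant SNPs into QTL.

    SNPs with ``p_value <= threshold_p`` are processed most significant
    first: each unassigned significant SNP becomes a lead and absorbs
    every unassigned significant SNP on the same chromosome within the
    window.  Clusters of at least three members (lead + >= 2
    supporters) are reported.  If the lead is a listed cofactor its
    scan statistics are degenerate, so the reported PVE is the maximum
    over the supporting members instead.

    ``window_mode='lead'`` uses +/- ``window_bp`` of the lead position;
    ``'bin'`` uses the fixed 1 Mb genome bin containing the lead.
    """
    if not (0.0 < threshold_p < 1.0):
        raise ValueError("threshold_p must lie in (0, 1)")
    if window_mode not in ("lead", "bin"):
        raise ValueError("window_mode must be 'lead' or 'bin'")
    cofactors = set(cofactors or [])

    sig = records[records["p_value"] <= threshold_p].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["p_value", "snp_id"], kind="stable").reset_index(drop=True)

    assigned = np.zeros(len(sig), dtype=bool)
    out: list[Qtl] = []
    for i in range(len(sig)):
        if assigned[i]:
            continue
        lead = sig.iloc[i]
        chrom = lead["chromosome"]
        pos = int(lead["position_bp"])
        if window_mode == "lead":
            lo, hi = pos - window_bp, pos + window_bp
        else:
            bin_start = (pos - 1) // window_bp * window_bp
            lo, hi = bin_start + 1, bin_start + window_bp
        members = (
            ~assigned
            & (sig["chromosome"] == chrom).to_numpy()
            & (sig["position_bp"].to_numpy() >= lo)
            & (sig["position_bp"].to_numpy() <= hi)
        )
        idx = np.flatnonzero(members)
        assigned[idx] = True  # consumed even if the cluster is too small
        if len(idx) < 3:
            continue
        cluster = sig.iloc[idx]
        supporters = cluster[cluster["snp_id"] != lead["snp_id"]]
        if lead["snp_id"] in cofactors and not supporters.empty:
            pve = float(supporters["pve"].max())
        else:
            pve = float(lead["pve"])
        out.append(
            Qtl(
                chromosome=int(chrom),
                label=_label(chrom, pos),
                lead_snp_id=str(lead["snp_id"]),
                lead_neglog10p=float(lead["neglog10p"]),
                lead_beta=float(lead["beta"]),
                pve=pve,
                supporting_snp_count=len(idx) - 1,
                member_snp_ids=sorted(cluster["snp_id"].tolist()),
            )
        )
    out.sort(key=lambda q: (-q.lead_neglog10p, q.label))
    return out


def qtl_table(qtls: list[Qtl]) -> pd.DataFrame:
    """Tabular view of called QTL (label, lead stats, PVE, support)."""
    return pd.DataFrame(
        [
            {
                "qtl": q.label,
                "chromosome": q.chromosome,
                "lead_snp_id": q.lead_snp_id,
                "neglog10p": q.lead_neglog10p,
                "beta": q.lead_beta,
                "pve": q.pve,
                "supporting_snps": q.supporting_snp_count,
            }
            for q in qtls
        ]
    )
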