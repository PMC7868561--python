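"""Promoter CpG methylation scoring and its pairing with TF occupancy.

Methylation is summarised as the mean beta (methylated fraction, in [0,1])
of the CpGs falling in a circRNA's −2 kb/+1 kb promoter window.  WGBS-mode
input carries a per-CpG read coverage and CpGs below a minimum coverage
(default 4) are excluded; 450k-array-mode betas carry no coverage and are
used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenomicInterval

MIN_WGBS_COVERAGE = 4

#: default equal-width beta bins for the occupancy stratification
DEFAULT_BETA_BINS = 5


@dataclass
class MethylationRecord:
    region_id: str
    mean_beta: float
    cpg_count: int

    @property
    def defined(self) -> bool:
        return self.cpg_count >= 1


def region_methylation(
    cpgs: pd.DataFrame,
    region: GenomicInterval,
    region_id: str = "",
    min_coverage: int = MIN_WGBS_COVERAGE,
    mode: str = "wgbs",
) -> MethylationRecord:
    """Mean beta of the qualifying CpGs inside ``region``.

    ``cpgs`` columns: chrom, pos, beta and (wgbs mode) coverage.  Zero
    qualifying CpGs yield an undefined record (cpg_count 0, beta nan) which
    downstream steps exclude.
    """
    sel = (
        (cpgs["chrom"] == region.chrom)
        & (cpgs["pos"] >= region.start)
        & (cpgs["pos"] < region.end)
    )
    sub = cpgs.loc[sel]
    if mode == "wgbs":
        sub = sub.loc[sub["coverage"] >= min_coverage]
    elif mode != "array":
        raise ValueError(f"unknown mode {mode!r}")
    if len(sub) == 0:
        return MethylationRecord(region_id, float("nan"), 0)
    beta = float(sub["beta"].mean())
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta outside [0,1] in region {region_id!r}")
    return MethylationRecord(region_id, beta, int(len(sub)))


def stratify_by_methylation(
    records: list[MethylationRecord],
    tf_degree: dict[str, int],
    n_bins: int = DEFAULT_BETA_BINS,
) -> pd.DataFrame:
    """Mean TF in-degree of circRNAs stratified by promoter beta.

    Records are binned into ``n_bins`` equal-width beta bins over [0, 1]
    (the last bin is closed).  Targets with no edges count degree 0.
    Returns one row per bin: bin_low, bin_high, n, mean_tf_count.
    """
    defined = [r for r in records if r.defined]
    if not defined:
        raise ValueError("no defined methylation records")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        if i < n_bins - 1:
            members = [r for r in defined if lo <= r.mean_beta < hi]
        else:
            members = [r for r in defined if lo <= r.mean_beta <= hi]
        degs = [tf_degree.get(r.region_id, 0) for r in members]
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n": len(members),
                "mean_tf_count": float(np.mean(degs)) if degs else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compare_tah_methylation(
    records: list[MethylationRecord],
    tah_ids,
) -> dict:
    """Mean promoter beta of TAH vs other circRNAs, with a one-sided
    Wilcoxon rank-sum test for TAH < other.

    The test is skipped (p = nan) when either group has < 2 defined records.
    """
    tah_ids = set(tah_ids)
    tah = [r.mean_beta for r in records if r.defined and r.region_id in tah_ids]
    other = [r.mean_beta for r in records if r.defined and r.region_id not in tah_ids]
    out = {
        "n_tah": len(tah),
        "n_other": len(other),
        "mean_beta_tah": float(np.mean(tah)) if tah else float("nan"),
        "mean_beta_other": float(np.mean(other)) if other else float("nan"),
        "p_value": float("nan"),
    }
    if len(tah) >= 2 and len(other) >= 2:
        out["p_value"] = float(sps.ranksums(tah, other, alternative="less").pvalue)
    return out


def methylation_activity_correlation(
    records: list[MethylationRecord],
    activity: dict[str, float],
) -> tuple[float, float]:
    """Spearman rho (and p) between promoter beta and promoter activity."""
    pairs = [
        (r.mean_beta, activity[r.region_id])
        for r in records
        if r.defined and r.region_id in activity
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired records")
    betas, acts = zip(*pairs)
    res = sps.spearmanr(betas, acts)
    return float(res.statistic), float(res.pvalue)
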