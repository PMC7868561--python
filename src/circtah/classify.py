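"""TAH-circRNA classification and circRNA-vs-host descriptive comparisons.

A TAH-circRNA ("Transcriptionally Activated to a Higher level than its
host") is a circRNA whose back-splice expression is strictly higher than the
host gene's linear expression AND whose promoter H3K27ac activity (RPKM_ss)
is strictly higher than the host promoter's.  Ties are not "higher"; the
strict rule keeps the call deterministic.

Two promoter-window conventions coexist in this analysis and are both named
here: the ±1 kb ``expression_window`` used by the RPKM_ss activity score
(its denominator is the fixed 2 kb window length) and the −2 kb/+1 kb
``tf_window`` used for TF occupancy, methylation scoring and ChIA-PET TSS
anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CircRNA, Gene, GenomicInterval
from .stats import hypergeometric_overlap

logger = logging.getLogger(__name__)

#: (upstream, downstream) extents of the two promoter-window conventions
WINDOW_CONVENTIONS: dict[str, tuple[int, int]] = {
    "expression_window": (1000, 1000),
    "tf_window": (2000, 1000),
}


@dataclass
class TahCall:
    """Classification of one circRNA against its host gene."""

    circ_id: str
    expr_higher: bool
    k27_higher: bool
    circ_host_fold: float

    @property
    def is_tah(self) -> bool:
        return self.expr_higher and self.k27_higher


def proximal_region(
    chrom: str, tss: int, strand: str, convention: str = "tf_window"
) -> GenomicInterval:
    """Strand-aware promoter window around a TSS, clipped at position 0."""
    try:
        up, down = WINDOW_CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown convention {convention!r}; "
            f"choose from {sorted(WINDOW_CONVENTIONS)}"
        ) from None
    if strand == "-":
        start, end = tss - down, tss + up
    else:
        start, end = tss - up, tss + down
    return GenomicInterval(chrom, max(0, start), end, strand)


def classify_tah(
    circ_rpkm: dict[str, float],
    host_rpkm: dict[str, float],
    circ_activity: dict[str, float],
    host_activity: dict[str, float],
) -> tuple[list[TahCall], dict]:
    """Apply the two-axis TAH rule to every circRNA with a resolvable host.

    All four mappings are keyed by circRNA id (host values are looked up per
    circRNA).  CircRNAs missing any of the four quantities are skipped with
    a log message.  Returns the calls plus a summary with the two marginal
    sets, their intersection, and the hypergeometric overlap p-value
    (upper tail, universe = classified circRNAs).
    """
    calls: list[TahCall] = []
    for cid, c_expr in circ_rpkm.items():
        if cid not in host_rpkm:
            logger.warning("circRNA %s: host expression missing; skipped", cid)
            continue
        if cid not in circ_activity or cid not in host_activity:
            logger.warning("circRNA %s: promoter activity missing; skipped", cid)
            continue
        h_expr = host_rpkm[cid]
        fold = c_expr / h_expr if h_expr > 0 else float("inf")
        calls.append(
            TahCall(
                circ_id=cid,
                expr_higher=c_expr > h_expr,
                k27_higher=circ_activity[cid] > host_activity[cid],
                circ_host_fold=fold,
            )
        )
    expr_set = {c.circ_id for c in calls if c.expr_higher}
    k27_set = {c.circ_id for c in calls if c.k27_higher}
    tah_set = expr_set & k27_set
    universe = len(calls)
    if universe > 0:
        overlap = hypergeometric_overlap(
            universe, len(expr_set), len(k27_set), len(tah_set)
        )
        p = overlap.p_value
    else:
        p = float("nan")
    summary = {
        "expr_higher": expr_set,
        "k27_higher": k27_set,
        "tah": tah_set,
        "universe": universe,
        "overlap_p": p,
    }
    return calls, summary


def calls_to_frame(calls: list[TahCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in calls],
            "expr_higher": [c.expr_higher for c in calls],
            "k27_higher": [c.k27_higher for c in calls],
            "circ_host_fold": [c.circ_host_fold for c in calls],
            "is_tah": [c.is_tah for c in calls],
        }
    )


def fold_change_spectrum(
    calls: list[TahCall], thresholds: list[float]
) -> dict[float, float]:
    """Fraction of circRNAs whose circ/host fold reaches each threshold.

    Infinite folds (host expression 0) exceed every finite threshold.
    Fractions are monotone non-increasing in the threshold.
    """
    if not calls:
        raise ValueError("empty call list")
    folds = np.array([c.circ_host_fold for c in calls])
    return {t: float(np.mean(folds >= t)) for t in thresholds}


def exon_count_distribution(
    circs: list[CircRNA], genes: list[Gene]
) -> pd.DataFrame:
    """Exon counts per circRNA (exons overlapped by its span) and per host.

    A circRNA overlapping no annotated exon counts as a single block.
    Returns one row per circRNA with a resolvable host.
    """
    gene_map = {g.id: g for g in genes}
    rows = []
    for c in circs:
        if c.host_gene is None or c.host_gene not in gene_map:
            continue
        g = gene_map[c.host_gene]
        n = sum(1 for a, b in g.exons if a < c.end and c.start < b)
        rows.append(
            {
                "circ_id": c.id,
                "host_gene": g.id,
                "circ_exons": max(n, 1),
                "host_exons": max(len(g.exons), 1),
            }
        )
    return pd.DataFrame(rows, columns=["circ_id", "host_gene", "circ_exons", "host_exons"])
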