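"""TF → circRNA and TF → gene occupancy networks.

A target (circRNA or gene) is occupied by a TF when at least one of the
TF's ChIP peaks intersects the target's −2 kb/+1 kb promoter window by at
least 1 bp.  Edges are deduplicated per (tf, target, cell line); multiple
replicate peak sets for the same TF in the same cell line collapse to one
edge set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import proximal_region
from .io import CircRNA, Gene, PeakSet

EDGE_COLUMNS = ["tf", "target", "kind", "cell_line"]


@dataclass
class DegreeFit:
    """Power-law fit of a degree histogram by log–log least squares."""

    histogram: dict[int, int]
    exponent: float
    r_squared: float
    degenerate: bool = False


def _window_index(targets, kind: str, convention: str = "tf_window"):
    """(chrom -> sorted arrays of window starts/ends + ids) for fast overlap."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for t in targets:
        w = proximal_region(t.chrom, t.tss, t.strand, convention)
        by_chrom.setdefault(t.chrom, []).append((w.start, w.end, t.id))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        ids = [r[2] for r in rows]
        out[chrom] = (starts, ends, ids)
    return out


def _occupied_targets(peaks: PeakSet, index) -> set[str]:
    hits: set[str] = set()
    for iv in peaks:
        if iv.chrom not in index:
            continue
        starts, ends, ids = index[iv.chrom]
        # windows have bounded length, so candidates are confined to
        # starts in [peak.start - max_window, peak.end)
        maxlen = int((ends - starts).max())
        lo = int(np.searchsorted(starts, iv.start - maxlen, side="left"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for j in range(lo, hi):
            if ends[j] > iv.start:
                hits.add(ids[j])
    return hits


def build_network(
    peaksets: dict[tuple[str, str], PeakSet],
    circs: list[CircRNA],
    genes: list[Gene],
    convention: str = "tf_window",
) -> pd.DataFrame:
    """Build the occupancy edge list.

    ``peaksets`` maps (tf, cell_line) to that TF's peaks in that cell line.
    Returns a DataFrame with columns tf, target, kind, cell_line — one row
    per deduplicated edge.
    """
    circ_idx = _window_index(circs, "circRNA", convention)
    gene_idx = _window_index(genes, "gene", convention)
    rows = []
    for (tf, cell), peaks in sorted(peaksets.items()):
        if len(peaks) == 0:
            import warnings

            warnings.warn(f"empty peak set for TF {tf!r} in {cell!r}")
            continue
        for target in sorted(_occupied_targets(peaks, circ_idx)):
            rows.append((tf, target, "circRNA", cell))
        for target in sorted(_occupied_targets(peaks, gene_idx)):
            rows.append((tf, target, "gene", cell))
    df = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return df.drop_duplicates().reset_index(drop=True)


def degree_distribution(edges: pd.DataFrame, all_targets=None) -> DegreeFit:
    """Per-target in-degree histogram with a log–log least-squares fit.

    The fitted exponent is the negated slope of log(frequency) on
    log(degree) over nonzero-degree bins; R² reports fit quality.  Isolated
    targets (degree 0, from ``all_targets``) appear in the histogram but are
    excluded from the fit.
    """
    deg = edges.groupby("target")["tf"].nunique()
    counts = deg.value_counts().to_dict()
    if all_targets is not None:
        n_zero = len(set(all_targets) - set(deg.index))
        if n_zero:
            counts[0] = n_zero
    if len(deg) < 10:
        raise ValueError("need >= 10 targets with edges for a degree fit")
    hist = {int(k): int(v) for k, v in sorted(counts.items())}
    pos = [(k, v) for k, v in hist.items() if k > 0]
    ks = np.array([k for k, _ in pos], dtype=float)
    vs = np.array([v for _, v in pos], dtype=float)
    if len(np.unique(ks)) < 2:
        return DegreeFit(hist, float("nan"), float("nan"), degenerate=True)
    res = sps.linregress(np.log(ks), np.log(vs))
    return DegreeFit(hist, -float(res.slope), float(res.rvalue) ** 2)


def shared_tf_partition(
    circ_edges: pd.DataFrame,
    gene_edges: pd.DataFrame,
    circ_host: dict[str, str],
) -> pd.DataFrame:
    """Per-circRNA sharing of TFs with its host gene.

    Labels: ``all`` (circ TF set ⊆ host TF set and equal), ``part`` (some
    but not all shared), ``none`` (disjoint).  CircRNAs with zero TFs are
    excluded and counted separately in the ``no_tf`` label.
    """
    circ_tfs = circ_edges.groupby("target")["tf"].agg(set).to_dict()
    gene_tfs = gene_edges.groupby("target")["tf"].agg(set).to_dict()
    rows = []
    for cid, host in circ_host.items():
        ctf = circ_tfs.get(cid, set())
        htf = gene_tfs.get(host, set()) if host is not None else set()
        if not ctf:
            label = "no_tf"
        else:
            shared = ctf & htf
            if not shared:
                label = "none"
            elif ctf == shared:
                label = "all"
            else:
                label = "part"
        rows.append({"circ_id": cid, "host_gene": host, "label": label})
    return pd.DataFrame(rows)


def cell_specificity_distribution(edges: pd.DataFrame) -> dict[int, int]:
    """Histogram of the number of cell lines supporting each (tf, target) pair."""
    n_lines = edges["cell_line"].nunique()
    if n_lines < 2:
        raise ValueError("need edges from >= 2 cell lines")
    per_pair = edges.groupby(["tf", "target"])["cell_line"].nunique()
    counts = per_pair.value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in range(1, n_lines + 1)}


def rank_tfs(edges: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """TFs ranked by number of occupied targets, for circRNAs and genes.

    Returns (circ ranking, gene ranking, Spearman rank correlation between
    the per-TF target counts on the two sides).
    """
    if edges.empty:
        raise ValueError("empty edge list")
    circ = (
        edges[edges["kind"] == "circRNA"]
        .groupby("tf")["target"]
        .nunique()
        .sort_values(ascending=False)
    )
    gene = (
        edges[edges["kind"] == "gene"]
        .groupby("tf")["target"]
        .nunique()
        .sort_values(ascending=False)
    )
    tfs = sorted(set(circ.index) | set(gene.index))
    if len(tfs) >= 2:
        rho = float(
            sps.spearmanr(
                [circ.get(t, 0) for t in tfs], [gene.get(t, 0) for t in tfs]
            ).statistic
        )
    else:
        rho = float("nan")
    return circ, gene, rho


def hub_targets(edges: pd.DataFrame, top_fraction: float = 0.1) -> set[str]:
    """Targets in the top decile of TF in-degree ('hub' circRNAs/genes)."""
    deg = edges.groupby("target")["tf"].nunique().sort_values(ascending=False)
    n = max(1, int(np.ceil(len(deg) * top_fraction)))
    cutoff = deg.iloc[n - 1]
    return set(deg[deg >= cutoff].index)
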