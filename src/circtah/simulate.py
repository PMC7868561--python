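"""Synthetic dataset generator with planted ground truth.

Emulates every input the pipeline consumes — circRNA/gene catalogs,
back-splice junction and gene-body read counts, H3K27ac coverage and peak
calls, per-TF ChIP peaks across cell lines, WGBS-style CpG tables,
ChIA-PET interaction pairs, microarray probe sequences and intensities,
and knockdown/control expression matrices — with a
:class:`SyntheticTruth` recording everything that was planted.

Geometry is engineered so that in the noise-free regime recovery is exact:

* genes are laid out with introns and intergenic gaps wide enough that the
  ±1 kb activity windows and −2/+1 kb TF windows of distinct TSSs never
  collide (circRNAs start at internal exons, so a circle's TSS is at least
  one exon+intron pitch away from its host's TSS);
* planted TF peaks are 300 bp rectangles centred on the target TSS, which
  places them inside exactly one promoter window;
* enhancer constituents live in intergenic zones more than 2 kb from every
  TSS, so ROSE-style TSS exclusion removes promoter peaks but keeps them;
* ChIA-PET anchors pair a circRNA's TSS window with a gene-promoter or
  enhancer peak at least ``min_contact_distance`` away.

Counts follow a negative-binomial model (Poisson-like at large dispersion);
``noise=0`` replaces all sampling with rounded means, making planted
classifications recoverable with precision = recall = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (
    CircRNA,
    Gene,
    GenomicInterval,
    InteractionPair,
    PeakSet,
    SignalTrack,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults define the study conditions."""

    # genome layout
    n_chroms: int = 4
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: int = 300
    intron_length: int = 3000
    intergenic: int = 20_000
    circs_per_gene: tuple[int, int] = (1, 3)
    generate_sequence: bool = True

    # expression
    fraction_tah: float = 0.25
    tah_expr_factor: float = 4.0
    nontah_expr_factor: float = 0.25
    se_expr_factor: float = 2.0
    host_rpkm_log_mean: float = math.log(5.0)
    host_rpkm_log_sd: float = 0.8
    min_host_rpkm: float = 1.0
    total_rna_reads: float = 1e7
    total_chip_reads: float = 1e7
    read_length: int = 75
    nb_dispersion: float = 20.0

    # H3K27ac
    k27_background: float = 0.4
    input_background: float = 0.2
    k27_scale: float = 0.4  # promoter peak height per unit host RPKM
    tah_k27_factor: float = 2.0
    nontah_k27_factor: float = 0.5
    promoter_peak_halfwidth: int = 500
    k27_jitter_sd: float = 0.25

    # TF network
    n_tf: int = 8
    cell_lines: tuple[str, ...] = ("CL1",)
    p_bind_tah: float = 0.6
    p_bind_other: float = 0.15
    p_bind_gene: float = 0.4
    lead_tf_boost: float = 1.5
    tf_peak_halfwidth: int = 150

    # super-enhancers
    se_gene_fraction: float = 0.10
    te_gene_fraction: float = 0.40
    se_constituents: tuple[int, int] = (4, 6)
    se_constituent_length: int = 800
    se_constituent_gap: int = 1500
    se_height: float = 8.0
    te_height: float = 1.0
    assign_window: int = 50_000

    # methylation
    meth_anticorr: float = 0.6
    meth_beta_low: float = 0.1
    meth_beta_high: float = 0.9
    cpgs_per_promoter: int = 12
    cpg_coverage_range: tuple[int, int] = (2, 30)
    cpg_beta_sd: float = 0.05

    # ChIA-PET
    contact_rate_tah: float = 0.5
    contact_rate_other: float = 0.1
    min_contact_distance: int = 12_000

    # knockdown experiment
    knockdown_factor: float = 2.0
    expr_noise_sd: float = 0.05
    n_expr_samples: int = 3

    # probes
    probed_fraction: float = 0.6
    probes_per_circ: tuple[int, int] = (1, 2)
    probe_length: int = 60
    n_decoy_probes: int = 15
    n_ambiguous_pairs: int = 2
    n_hcc_samples: int = 6

    # global
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_tah", "p_bind_tah", "p_bind_other", "p_bind_gene",
            "contact_rate_tah", "contact_rate_other", "probed_fraction",
            "se_gene_fraction", "te_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("tah_expr_factor", "nontah_expr_factor", "se_expr_factor",
                     "tah_k27_factor", "nontah_k27_factor", "knockdown_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        cluster = (
            self.se_constituents[1] * self.se_constituent_length
            + (self.se_constituents[1] - 1) * self.se_constituent_gap
        )
        if cluster + 5000 > self.intergenic:
            raise ValueError(
                "intergenic gap too small to hold a super-enhancer cluster"
            )


@dataclass
class SyntheticTruth:
    """Everything planted, for recovery tests."""

    tah_ids: set = field(default_factory=set)
    tf_edges: set = field(default_factory=set)  # (cell, tf, target, kind)
    se_intervals: list = field(default_factory=list)
    se_assoc: set = field(default_factory=set)
    te_assoc: set = field(default_factory=set)
    contact_ids: set = field(default_factory=set)
    responsive_ids: set = field(default_factory=set)
    lead_tf: str = ""
    probe_map: dict = field(default_factory=dict)  # probe -> circ
    decoy_probes: set = field(default_factory=set)
    ambiguous_probes: set = field(default_factory=set)
    planted_intensities: pd.DataFrame | None = None
    circ_ratio: dict = field(default_factory=dict)  # circ -> planted factor


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list
    circs: list
    genome: dict | None
    chrom_lengths: dict
    junction_reads: dict
    body_reads: dict
    k27_track: SignalTrack
    input_track: SignalTrack
    k27_peaks: PeakSet
    tf_peaks: dict  # (tf, cell) -> PeakSet
    cpgs: pd.DataFrame
    pairs: list
    probes: dict
    probe_intensities: pd.DataFrame
    control_matrix: pd.DataFrame
    knockdown_matrix: pd.DataFrame
    truth: SyntheticTruth


def _counts(rng, mean: np.ndarray, dispersion: float, noise: float) -> np.ndarray:
    """NB counts at the given means; rounded means when noise = 0."""
    mean = np.asarray(mean, dtype=float)
    if noise == 0:
        return np.rint(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    out = np.where(mean > 0, rng.negative_binomial(dispersion, np.clip(p, 1e-12, 1.0)), 0)
    return out.astype(np.int64)


def _jitter(rng, n: int, sd: float, noise: float) -> np.ndarray:
    if noise == 0 or sd == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, sd * noise, size=n))


def _build_track(
    chrom_lengths: dict[str, int],
    rects: dict[str, list[tuple[int, int, float]]],
    background: float,
    total_reads: float,
) -> SignalTrack:
    """Piecewise-constant track = background + sum of rectangles."""
    runs = {}
    for chrom, length in chrom_lengths.items():
        events: dict[int, float] = {0: 0.0, length: 0.0}
        for start, end, h in rects.get(chrom, ()):
            start, end = max(0, start), min(length, end)
            if end <= start:
                continue
            events[start] = events.get(start, 0.0) + h
            events[end] = events.get(end, 0.0) - h
        pos = np.array(sorted(events), dtype=np.int64)
        deltas = np.array([events[p] for p in pos])
        level = background + np.cumsum(deltas)[:-1]
        starts, ends, values = pos[:-1], pos[1:], level
        keep = values > 0
        runs[chrom] = (starts[keep], ends[keep], values[keep])
    return SignalTrack(runs, total_reads)


def _random_sequence(rng, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return _BASES[idx].tobytes().decode()


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset (see module docstring)."""
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # ------------------------------------------------------------------ layout
    genes: list[Gene] = []
    circs: list[CircRNA] = []
    gene_chrom: dict[str, str] = {}
    chrom_cursor: dict[str, int] = {}
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    for c in chrom_names:
        chrom_cursor[c] = 0
    gap_start: dict[str, int] = {}  # gene id -> start of its upstream gap

    pitch = cfg.exon_length + cfg.intron_length
    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi % cfg.n_chroms]
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{gi:05d}"
        gap_start[gid] = chrom_cursor[chrom]
        start = chrom_cursor[chrom] + cfg.intergenic
        exons = tuple(
            (start + j * pitch, start + j * pitch + cfg.exon_length)
            for j in range(n_ex)
        )
        end = exons[-1][1]
        genes.append(Gene(gid, chrom, start, end, strand, exons))
        gene_chrom[gid] = chrom
        chrom_cursor[chrom] = end

        n_circ = int(rng.integers(cfg.circs_per_gene[0], cfg.circs_per_gene[1] + 1))
        # the circle's TSS-side exon must be internal so its TSS is a full
        # exon+intron pitch away from the host TSS
        if strand == "+":
            avail = list(range(1, n_ex))
        else:
            avail = list(range(0, n_ex - 1))
        n_circ = min(n_circ, len(avail))
        chosen = rng.choice(avail, size=n_circ, replace=False)
        for k, anchor in enumerate(sorted(int(a) for a in chosen)):
            span = int(rng.integers(1, 4))  # 1-3 exons
            if strand == "+":
                s_ex = anchor
                e_ex = min(anchor + span - 1, n_ex - 1)
            else:
                e_ex = anchor
                s_ex = max(anchor - span + 1, 0)
            cid = f"circ_{gi:05d}_{k}"
            circs.append(
                CircRNA(cid, chrom, exons[s_ex][0], exons[e_ex][1], strand, gid)
            )
    for c in chrom_names:
        chrom_cursor[c] += cfg.intergenic  # trailing gap
    chrom_lengths = dict(chrom_cursor)

    circ_by_id = {c.id: c for c in circs}
    n_circ_total = len(circs)

    # ------------------------------------------------------------ planted TAH
    n_tah = int(round(cfg.fraction_tah * n_circ_total))
    tah_idx = rng.choice(n_circ_total, size=n_tah, replace=False)
    tah_ids = {circs[int(i)].id for i in tah_idx}

    # ------------------------------------------------- enhancer zones per gene
    se_genes: set[str] = set()
    te_genes: set[str] = set()
    se_intervals: list[GenomicInterval] = []
    enh_rects: dict[str, list[tuple[int, int, float]]] = {}
    enh_peaks: list[GenomicInterval] = []
    # planted stitched-region spans with flavour and signal load, for truth
    planted_regions: list[tuple[GenomicInterval, str, float]] = []
    u = rng.random(cfg.n_genes)
    for gi, g in enumerate(genes):
        zone = gap_start[g.id] + 2500  # keeps constituents > 2 kb from TSSs
        if u[gi] < cfg.se_gene_fraction:
            se_genes.add(g.id)
            n_con = int(rng.integers(cfg.se_constituents[0], cfg.se_constituents[1] + 1))
            pos = zone
            cluster = []
            for _ in range(n_con):
                iv = GenomicInterval(g.chrom, pos, pos + cfg.se_constituent_length)
                cluster.append(iv)
                pos = iv.end + cfg.se_constituent_gap
            span = GenomicInterval(g.chrom, cluster[0].start, cluster[-1].end)
            se_intervals.append(span)
            enh_peaks.extend(cluster)
            h = cfg.se_height * float(_jitter(rng, 1, cfg.k27_jitter_sd, cfg.noise)[0])
            enh_rects.setdefault(g.chrom, []).extend(
                (iv.start, iv.end, h) for iv in cluster
            )
            load = sum((h - cfg.input_background) * len(iv) for iv in cluster)
            planted_regions.append((span, "SE", load))
        elif u[gi] < cfg.se_gene_fraction + cfg.te_gene_fraction:
            te_genes.add(g.id)
            iv = GenomicInterval(g.chrom, zone, zone + cfg.se_constituent_length)
            enh_peaks.append(iv)
            h = cfg.te_height * float(_jitter(rng, 1, cfg.k27_jitter_sd, cfg.noise)[0])
            enh_rects.setdefault(g.chrom, []).append((iv.start, iv.end, h))
            planted_regions.append(
                (iv, "TE", (h - cfg.input_background) * len(iv))
            )

    # truth labels replicate the assignment rule over the planted regions:
    # nearest region with span overlap or TSS within the window, ties to
    # the higher signal load
    se_assoc: set[str] = set()
    te_assoc: set[str] = set()
    regions_by_chrom: dict[str, list[tuple[GenomicInterval, str, float]]] = {}
    for reg in planted_regions:
        regions_by_chrom.setdefault(reg[0].chrom, []).append(reg)
    for c in circs:
        best = None
        for iv, flavour, load in regions_by_chrom.get(c.chrom, ()):
            if iv.start < c.end and c.start < iv.end:
                dist = 0
            else:
                dist = max(iv.start - c.tss, c.tss - iv.end, 0)
                if dist > cfg.assign_window:
                    continue
            key = (dist, -load)
            if best is None or key < best[0]:
                best = (key, flavour)
        if best is not None:
            (se_assoc if best[1] == "SE" else te_assoc).add(c.id)

    # -------------------------------------------------------------- expression
    host_rpkm = np.maximum(
        rng.lognormal(cfg.host_rpkm_log_mean, cfg.host_rpkm_log_sd, cfg.n_genes),
        cfg.min_host_rpkm,
    )
    host_rpkm_by_id = {g.id: float(r) for g, r in zip(genes, host_rpkm)}
    gene_lengths = {g.id: g.end - g.start for g in genes}
    body_mean = np.array(
        [host_rpkm_by_id[g.id] * cfg.total_rna_reads * gene_lengths[g.id] / 1e9
         for g in genes]
    )
    body_reads = {
        g.id: int(max(1, m))
        for g, m in zip(genes, _counts(rng, body_mean, cfg.nb_dispersion, cfg.noise))
    }
    realized_host_rpkm = {
        g.id: 1e9 * body_reads[g.id] / (cfg.total_rna_reads * gene_lengths[g.id])
        for g in genes
    }

    circ_ratio: dict[str, float] = {}
    junction_mean = np.empty(n_circ_total)
    for i, c in enumerate(circs):
        ratio = cfg.tah_expr_factor if c.id in tah_ids else cfg.nontah_expr_factor
        if c.id in se_assoc:
            ratio *= cfg.se_expr_factor
        circ_ratio[c.id] = ratio
        target_rpkm = ratio * realized_host_rpkm[c.host_gene]
        # invert rpkm = (j / N * 1e6) / 112 * 1000
        junction_mean[i] = target_rpkm * 112.0 * cfg.total_rna_reads / 1e9
    junction_reads = {
        c.id: int(j)
        for c, j in zip(circs, _counts(rng, junction_mean, cfg.nb_dispersion, cfg.noise))
    }

    # ------------------------------------------------------------ H3K27ac track
    prom_rects: dict[str, list[tuple[int, int, float]]] = {}
    prom_peaks: list[GenomicInterval] = []
    hw = cfg.promoter_peak_halfwidth
    gene_height: dict[str, float] = {}
    jit = _jitter(rng, cfg.n_genes, cfg.k27_jitter_sd, cfg.noise)
    for g, jg in zip(genes, jit):
        h = cfg.k27_scale * host_rpkm_by_id[g.id] * float(jg)
        gene_height[g.id] = h
        iv = GenomicInterval(g.chrom, max(0, g.tss - hw), g.tss + hw)
        prom_peaks.append(iv)
        prom_rects.setdefault(g.chrom, []).append((iv.start, iv.end, h))
    circ_height: dict[str, float] = {}
    jit = _jitter(rng, n_circ_total, cfg.k27_jitter_sd, cfg.noise)
    for c, jc in zip(circs, jit):
        factor = cfg.tah_k27_factor if c.id in tah_ids else cfg.nontah_k27_factor
        base = cfg.k27_scale * host_rpkm_by_id[c.host_gene]
        h = base * factor * float(jc)
        circ_height[c.id] = h
        iv = GenomicInterval(c.chrom, max(0, c.tss - hw), c.tss + hw)
        prom_peaks.append(iv)
        prom_rects.setdefault(c.chrom, []).append((iv.start, iv.end, h))

    all_rects: dict[str, list[tuple[int, int, float]]] = {}
    for d in (prom_rects, enh_rects):
        for chrom, rs in d.items():
            all_rects.setdefault(chrom, []).extend(rs)
    k27_track = _build_track(
        chrom_lengths, all_rects, cfg.k27_background, cfg.total_chip_reads
    )
    input_track = _build_track(
        chrom_lengths, {}, cfg.input_background, cfg.total_chip_reads
    )
    k27_peaks = PeakSet(sorted(prom_peaks + enh_peaks)).sorted()

    # ---------------------------------------------------------------- TF peaks
    tf_names = [f"TF{i + 1}" for i in range(cfg.n_tf)]
    lead_tf = tf_names[0]
    tf_peaks: dict[tuple[str, str], PeakSet] = {}
    tf_edges: set[tuple[str, str, str, str]] = set()
    thw = cfg.tf_peak_halfwidth
    for cell in cfg.cell_lines:
        for t_i, tf in enumerate(tf_names):
            boost = cfg.lead_tf_boost if tf == lead_tf else 1.0
            ivs: list[GenomicInterval] = []
            for c in circs:
                p = min(0.95, boost * (cfg.p_bind_tah if c.id in tah_ids
                                       else cfg.p_bind_other))
                if rng.random() < p:
                    ivs.append(
                        GenomicInterval(c.chrom, max(0, c.tss - thw), c.tss + thw)
                    )
                    tf_edges.add((cell, tf, c.id, "circRNA"))
            for g in genes:
                p = min(0.95, boost * cfg.p_bind_gene)
                if rng.random() < p:
                    ivs.append(
                        GenomicInterval(g.chrom, max(0, g.tss - thw), g.tss + thw)
                    )
                    tf_edges.add((cell, tf, g.id, "gene"))
            tf_peaks[(tf, cell)] = PeakSet(ivs).sorted()

    # -------------------------------------------------------------- methylation
    heights = np.array([circ_height[c.id] for c in circs])
    ranks = sps.rankdata(heights, method="average")
    z_act = sps.norm.ppf((ranks - 0.5) / n_circ_total)
    r = cfg.meth_anticorr
    eps = rng.normal(size=n_circ_total)
    z_beta = -r * z_act + math.sqrt(max(0.0, 1 - r * r)) * eps
    beta_mean = cfg.meth_beta_low + (cfg.meth_beta_high - cfg.meth_beta_low) * (
        sps.norm.cdf(z_beta)
    )
    cpg_rows = []
    for c, bm in zip(circs, beta_mean):
        if c.strand == "+":
            lo, hi = c.tss - 2000, c.tss + 1000
        else:
            lo, hi = c.tss - 1000, c.tss + 2000
        positions = np.linspace(lo + 50, hi - 50, cfg.cpgs_per_promoter).astype(int)
        betas = np.clip(
            bm + cfg.cpg_beta_sd * cfg.noise * rng.normal(size=len(positions)),
            0.0,
            1.0,
        )
        covs = rng.integers(
            cfg.cpg_coverage_range[0], cfg.cpg_coverage_range[1] + 1,
            size=len(positions),
        )
        for p_, b_, cv_ in zip(positions, betas, covs):
            cpg_rows.append((c.chrom, int(p_), float(b_), int(cv_)))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "beta", "coverage"])
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # ----------------------------------------------------------------- ChIA-PET
    # candidate distal anchors: gene promoter peaks and enhancer constituents
    anchor_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        iv = GenomicInterval(g.chrom, max(0, g.tss - hw), g.tss + hw)
        anchor_by_chrom.setdefault(g.chrom, []).append(iv)
    for iv in enh_peaks:
        anchor_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in anchor_by_chrom:
        anchor_by_chrom[chrom].sort(key=lambda iv: iv.midpoint())
    pairs: list[InteractionPair] = []
    contact_ids: set[str] = set()
    for c in circs:
        rate = cfg.contact_rate_tah if c.id in tah_ids else cfg.contact_rate_other
        if rng.random() >= rate:
            continue
        a1 = GenomicInterval(c.chrom, max(0, c.tss - 500), c.tss + 100)
        mid1 = a1.midpoint()
        candidates = [
            iv for iv in anchor_by_chrom.get(c.chrom, ())
            if abs(iv.midpoint() - mid1) >= cfg.min_contact_distance
        ]
        if not candidates:
            continue
        a2 = min(candidates, key=lambda iv: abs(iv.midpoint() - mid1))
        pairs.append(InteractionPair(a1, a2))
        contact_ids.add(c.id)
    # decoy pairs in safe intergenic margins exercise the filters
    n_decoy_pairs = int(round(10 * cfg.noise))
    decoy_genes = rng.choice(cfg.n_genes, size=min(n_decoy_pairs, cfg.n_genes),
                             replace=False)
    for gi in decoy_genes:
        g = genes[int(gi)]
        m = gap_start[g.id] + cfg.intergenic - 3000
        a1 = GenomicInterval(g.chrom, m, m + 300)
        a2 = GenomicInterval(g.chrom, max(0, m - 4000), max(0, m - 4000) + 300)
        pairs.append(InteractionPair(a1, a2))

    # ------------------------------------------------------------------- probes
    genome: dict[str, str] | None = None
    probes: dict[str, str] = {}
    probe_map: dict[str, str] = {}
    decoy_probes: set[str] = set()
    ambiguous_probes: set[str] = set()
    planted_intensities = None
    probe_intensities = pd.DataFrame()
    if cfg.generate_sequence:
        genome = {c: _random_sequence(rng, L) for c, L in chrom_lengths.items()}
        # twins: pairs of single-exon plus-strand circles given identical
        # junction context so their probes become ambiguous
        single_plus = [
            c for c in circs
            if c.strand == "+" and (c.end - c.start) == cfg.exon_length
        ]
        twins: list[tuple[CircRNA, CircRNA]] = []
        for i in range(cfg.n_ambiguous_pairs):
            if len(single_plus) < 2:
                break
            a = single_plus.pop(0)
            b = single_plus.pop(0)
            ga = genome[a.chrom]
            gb = genome[b.chrom]
            genome[b.chrom] = (
                gb[: b.start] + ga[a.start : a.start + 45]
                + gb[b.start + 45 : b.end - 45]
                + ga[a.end - 45 : a.end] + gb[b.end :]
            )
            twins.append((a, b))
        twin_ids = {c.id for pair in twins for c in pair}

        from .probes import build_junction_library

        library = build_junction_library(circs, genome, genes)
        junc_by_id = {j.circ_id: j for j in library}
        eligible = [c for c in circs if c.id not in twin_ids]
        n_probed = int(round(cfg.probed_fraction * len(eligible)))
        probed = rng.choice(len(eligible), size=n_probed, replace=False)
        pn = 0
        for i in sorted(int(i) for i in probed):
            c = eligible[i]
            j = junc_by_id[c.id]
            span = len(j.sequence)
            if span < cfg.probe_length:
                continue
            k = int(rng.integers(cfg.probes_per_circ[0], cfg.probes_per_circ[1] + 1))
            # any full-length window of a 90-mer crosses the centre junction
            max_off = span - cfg.probe_length
            offs = rng.integers(0, max_off + 1, size=k)
            for off in sorted(set(int(o) for o in offs)):
                pid = f"probe_{pn:05d}"
                pn += 1
                probes[pid] = j.sequence[off : off + cfg.probe_length]
                probe_map[pid] = c.id
        for _ in range(cfg.n_decoy_probes):
            pid = f"decoy_{pn:05d}"
            pn += 1
            probes[pid] = _random_sequence(rng, cfg.probe_length)
            decoy_probes.add(pid)
        for a, b in twins:
            j = junc_by_id[a.id]
            pid = f"ambig_{pn:05d}"
            pn += 1
            off = int(rng.integers(0, len(j.sequence) - cfg.probe_length + 1))
            probes[pid] = j.sequence[off : off + cfg.probe_length]
            ambiguous_probes.add(pid)

        # intensity table: every probe of a circRNA carries the circle's
        # planted per-sample value exactly, so collapsing recovers it
        samples = [f"HCC_{i + 1}" for i in range(cfg.n_hcc_samples)]
        circ_vals = {}
        for cid in sorted(set(probe_map.values())):
            circ_vals[cid] = np.round(
                rng.lognormal(2.0, 0.5, size=cfg.n_hcc_samples), 4
            )
        planted_intensities = pd.DataFrame(circ_vals, index=samples).T
        planted_intensities.columns = samples
        rows = {}
        for pid in probes:
            if pid in probe_map:
                rows[pid] = planted_intensities.loc[probe_map[pid]].to_numpy()
            else:
                rows[pid] = np.round(rng.lognormal(2.0, 0.5, cfg.n_hcc_samples), 4)
        probe_intensities = pd.DataFrame.from_dict(rows, orient="index",
                                                   columns=samples)

    # -------------------------------------------------------- knockdown matrix
    responsive = {
        c.id for c in circs
        if c.id in tah_ids
        and (cfg.cell_lines[0], lead_tf, c.id, "circRNA") in tf_edges
    }
    features = [c.id for c in circs] + [g.id for g in genes]
    base_vals = np.array(
        [
            circ_ratio[f] * realized_host_rpkm[circ_by_id[f].host_gene]
            if f in circ_by_id
            else realized_host_rpkm[f]
            for f in features
        ]
    )
    kd_vals = base_vals.copy()
    for i, f in enumerate(features):
        if f in responsive:
            kd_vals[i] /= cfg.knockdown_factor
    ns = cfg.n_expr_samples
    ctrl = base_vals[:, None] * _jitter(
        rng, len(features) * ns, cfg.expr_noise_sd, cfg.noise
    ).reshape(len(features), ns)
    kd = kd_vals[:, None] * _jitter(
        rng, len(features) * ns, cfg.expr_noise_sd, cfg.noise
    ).reshape(len(features), ns)
    cols_c = [f"control_{i + 1}" for i in range(ns)]
    cols_k = [f"knockdown_{i + 1}" for i in range(ns)]
    control_matrix = pd.DataFrame(ctrl, index=features, columns=cols_c)
    knockdown_matrix = pd.DataFrame(kd, index=features, columns=cols_k)

    truth = SyntheticTruth(
        tah_ids=tah_ids,
        tf_edges=tf_edges,
        se_intervals=se_intervals,
        se_assoc=se_assoc,
        te_assoc=te_assoc,
        contact_ids=contact_ids,
        responsive_ids=responsive,
        lead_tf=lead_tf,
        probe_map=probe_map,
        decoy_probes=decoy_probes,
        ambiguous_probes=ambiguous_probes,
        planted_intensities=planted_intensities,
        circ_ratio=circ_ratio,
    )
    return SyntheticDataset(
        config=cfg,
        genes=genes,
        circs=circs,
        genome=genome,
        chrom_lengths=chrom_lengths,
        junction_reads=junction_reads,
        body_reads=body_reads,
        k27_track=k27_track,
        input_track=input_track,
        k27_peaks=k27_peaks,
        tf_peaks=tf_peaks,
        cpgs=cpgs,
        pairs=pairs,
        probes=probes,
        probe_intensities=probe_intensities,
        control_matrix=control_matrix,
        knockdown_matrix=knockdown_matrix,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every component of a dataset in the formats the readers accept.

    Output is deterministic: generating with the same seed and writing
    twice yields byte-identical files.
    """
    import json
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    cio.write_circ_catalog(dataset.circs, p("circs.tsv"))
    cio.write_gene_catalog(dataset.genes, p("genes.tsv"))
    with open(p("junction_counts.tsv"), "w") as fh:
        fh.write("id\treads\n")
        for c in dataset.circs:
            fh.write(f"{c.id}\t{dataset.junction_reads.get(c.id, 0)}\n")
    with open(p("body_counts.tsv"), "w") as fh:
        fh.write("id\treads\n")
        for g in dataset.genes:
            fh.write(f"{g.id}\t{dataset.body_reads.get(g.id, 0)}\n")
    cio.write_bedgraph(dataset.k27_track, p("k27.bedgraph"))
    cio.write_bedgraph(dataset.input_track, p("input.bedgraph"))
    cio.write_bed(dataset.k27_peaks, p("k27_peaks.bed"))
    for (tf, cell), peaks in sorted(dataset.tf_peaks.items()):
        cio.write_bed(peaks, p(f"tf_{tf}_{cell}.bed"))
    dataset.cpgs.to_csv(p("cpgs.tsv"), sep="\t", index=False)
    cio.write_bedpe(dataset.pairs, p("interactions.bedpe"))
    if dataset.genome is not None:
        cio.write_fasta(dataset.probes, p("probes.fa"))
        dataset.probe_intensities.to_csv(p("probe_intensities.tsv"), sep="\t")
    dataset.control_matrix.to_csv(p("control_matrix.tsv"), sep="\t")
    dataset.knockdown_matrix.to_csv(p("knockdown_matrix.tsv"), sep="\t")
    truth = dataset.truth
    with open(p("truth.json"), "w") as fh:
        json.dump(
            {
                "tah_ids": sorted(truth.tah_ids),
                "tf_edges": sorted(map(list, truth.tf_edges)),
                "se_intervals": [
                    [iv.chrom, iv.start, iv.end] for iv in truth.se_intervals
                ],
                "se_assoc": sorted(truth.se_assoc),
                "te_assoc": sorted(truth.te_assoc),
                "contact_ids": sorted(truth.contact_ids),
                "responsive_ids": sorted(truth.responsive_ids),
                "lead_tf": truth.lead_tf,
                "probe_map": truth.probe_map,
                "decoy_probes": sorted(truth.decoy_probes),
                "ambiguous_probes": sorted(truth.ambiguous_probes),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
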