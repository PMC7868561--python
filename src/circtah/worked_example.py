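"""A tiny fixed dataset whose every number is checkable by hand.

Ten circRNAs over five genes on one chromosome, two TFs, one
super-enhancer cluster and two typical enhancers.  The RNA library holds
10^6 reads, so each circle's junction count equals its RPM; the ChIP read
length is 50 bp and promoter peaks are 1 kb rectangles of hand-set
heights, so RPKM_ss = 10 × height.

Layout (all '+' strand except gene g3):

* genes g1..g5: five 300 bp exons, 3 kb introns, starts at 10 kb + 30 kb
  steps, so gene k spans [10000 + 30000(k-1), +13500);
* circRNAs sit on internal exons, so each circle's TSS is 3.3 kb or more
  from its host's TSS;
* the SE cluster (three 800 bp constituents at 2500/4500/6500, height 10)
  stitches to [2500, 7300); two lone TE peaks (height 1) sit near g4 and
  g5; one ChIA-PET pair links circ c01's TSS window to an SE constituent.

Planted TAH set: {c01, c03, c05, c07, c09}.  c10 has higher promoter
activity but lower expression than its host; c02/c04/c06/c08 are higher on
neither axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CircRNA, Gene, GenomicInterval, InteractionPair, PeakSet
from .simulate import SyntheticDataset, SyntheticConfig, SyntheticTruth, _build_track, _random_sequence

TOTAL_RNA_READS = 1_000_000
TOTAL_CHIP_READS = 1_000_000
READ_LENGTH = 50
CHROM = "chr1"
CHROM_LENGTH = 160_000

#: planted TAH ids
TAH_IDS = frozenset({"c01", "c03", "c05", "c07", "c09"})

# id, host, start exon, end exon (0-based), junction reads, promoter peak height
_CIRC_SPEC = [
    ("c01", "g1", 1, 2, 56, 2.0),
    ("c02", "g1", 3, 3, 5, 0.5),
    ("c03", "g2", 1, 1, 28, 4.0),
    ("c04", "g2", 2, 2, 0, 1.0),
    ("c05", "g3", 2, 3, 112, 3.0),
    ("c06", "g3", 1, 1, 11, 0.5),
    ("c07", "g4", 1, 3, 14, 1.0),
    ("c08", "g4", 2, 2, 1, 0.2),
    ("c09", "g5", 1, 1, 45, 4.0),
    ("c10", "g5", 3, 3, 2, 4.0),
]

# gene id, strand, gene-body reads, promoter peak height
_GENE_SPEC = [
    ("g1", "+", 1350, 1.0),
    ("g2", "+", 675, 2.0),
    ("g3", "-", 2700, 1.0),
    ("g4", "+", 135, 0.5),
    ("g5", "+", 1350, 2.0),
]

_SE_CONSTITUENTS = [(2500, 3300), (4500, 5300), (6500, 7300)]
_TE_PEAKS = [(95_000, 95_800), (125_000, 125_800)]
_SE_HEIGHT = 10.0
_TE_HEIGHT = 1.0


def _gene(gi: int, strand: str) -> Gene:
    start = 10_000 + 30_000 * gi
    exons = tuple((start + j * 3300, start + j * 3300 + 300) for j in range(5))
    return Gene(f"g{gi + 1}", CHROM, start, exons[-1][1], strand, exons)


def generate_worked_example() -> SyntheticDataset:
    """Build the fixture; identical output on every call."""
    genes = [_gene(i, strand) for i, (_, strand, _, _) in enumerate(_GENE_SPEC)]
    gene_map = {g.id: g for g in genes}
    circs = []
    for cid, host, s_ex, e_ex, _, _ in _CIRC_SPEC:
        g = gene_map[host]
        circs.append(
            CircRNA(cid, CHROM, g.exons[s_ex][0], g.exons[e_ex][1], g.strand, host)
        )
    junction_reads = {cid: j for cid, _, _, _, j, _ in _CIRC_SPEC}
    body_reads = {gid: m for gid, _, m, _ in _GENE_SPEC}

    hw = 500
    rects = []
    prom_peaks = []
    for g, (_, _, _, h) in zip(genes, _GENE_SPEC):
        rects.append((g.tss - hw, g.tss + hw, h))
        prom_peaks.append(GenomicInterval(CHROM, g.tss - hw, g.tss + hw))
    for c, (_, _, _, _, _, h) in zip(circs, _CIRC_SPEC):
        rects.append((c.tss - hw, c.tss + hw, h))
        prom_peaks.append(GenomicInterval(CHROM, c.tss - hw, c.tss + hw))
    enh_peaks = [GenomicInterval(CHROM, a, b) for a, b in _SE_CONSTITUENTS]
    enh_peaks += [GenomicInterval(CHROM, a, b) for a, b in _TE_PEAKS]
    rects += [(a, b, _SE_HEIGHT) for a, b in _SE_CONSTITUENTS]
    rects += [(a, b, _TE_HEIGHT) for a, b in _TE_PEAKS]
    chrom_lengths = {CHROM: CHROM_LENGTH}
    k27_track = _build_track(chrom_lengths, {CHROM: rects}, 0.0, TOTAL_CHIP_READS)
    input_track = _build_track(chrom_lengths, {}, 0.0, TOTAL_CHIP_READS)
    k27_peaks = PeakSet(sorted(prom_peaks + enh_peaks)).sorted()

    circ_map = {c.id: c for c in circs}
    tf_edges = {
        ("HepG2", "TF_A", cid, "circRNA") for cid in sorted(TAH_IDS)
    } | {
        ("HepG2", "TF_A", "g1", "gene"),
        ("HepG2", "TF_B", "c01", "circRNA"),
        ("HepG2", "TF_B", "c05", "circRNA"),
        ("HepG2", "TF_B", "g3", "gene"),
    }
    tf_peaks = {}
    for tf in ("TF_A", "TF_B"):
        ivs = []
        for (_, tf_, target, kind) in sorted(tf_edges):
            if tf_ != tf:
                continue
            t = circ_map[target] if kind == "circRNA" else gene_map[target]
            ivs.append(GenomicInterval(CHROM, t.tss - 150, t.tss + 150))
        tf_peaks[(tf, "HepG2")] = PeakSet(ivs).sorted()

    # CpGs: TAH promoters at beta 0.2, others 0.7; one low-coverage CpG per
    # promoter (coverage 3, beta 1.0) exercises the WGBS filter
    cpg_rows = []
    for c in circs:
        beta = 0.2 if c.id in TAH_IDS else 0.7
        for off in (-1500, -500, 500):
            cpg_rows.append((CHROM, c.tss + off, beta, 10))
        cpg_rows.append((CHROM, c.tss + 100, 1.0, 3))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "beta", "coverage"])
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    c01 = circ_map["c01"]
    pairs = [
        InteractionPair(
            GenomicInterval(CHROM, c01.tss - 500, c01.tss + 100),
            GenomicInterval(CHROM, 2500, 3300),
        )
    ]

    genome = {CHROM: _random_sequence(np.random.default_rng(42), CHROM_LENGTH)}
    from .probes import build_junction_library

    library = build_junction_library(circs, genome, genes)
    junc = {j.circ_id: j for j in library}
    probes = {
        "p_c01_a": junc["c01"].sequence[0:60],
        "p_c01_b": junc["c01"].sequence[20:80],
        "p_c03": junc["c03"].sequence[10:70],
        "p_decoy": _random_sequence(np.random.default_rng(7), 60),
    }
    probe_map = {"p_c01_a": "c01", "p_c01_b": "c01", "p_c03": "c03"}
    samples = ["HCC_1", "HCC_2"]
    probe_intensities = pd.DataFrame(
        {
            "p_c01_a": [4.0, 6.0],
            "p_c01_b": [6.0, 6.0],
            "p_c03": [3.0, 5.0],
            "p_decoy": [1.0, 1.0],
        },
        index=samples,
    ).T

    features = [c.id for c in circs] + [g.id for g in genes]
    base = {
        **{c.id: 10.0 for c in circs},
        **{g.id: 10.0 for g in genes},
    }
    responsive = {"c01", "c05"}
    ctrl = pd.DataFrame(
        {f"control_{i}": [base[f] for f in features] for i in (1, 2, 3)},
        index=features,
    )
    kd = ctrl.copy()
    kd.columns = ["knockdown_1", "knockdown_2", "knockdown_3"]
    for f in responsive:
        kd.loc[f] = 5.0

    config = SyntheticConfig(
        n_chroms=1,
        n_genes=len(genes),
        total_rna_reads=TOTAL_RNA_READS,
        total_chip_reads=TOTAL_CHIP_READS,
        read_length=READ_LENGTH,
        cell_lines=("HepG2",),
        noise=0.0,
        seed=42,
    )
    truth = SyntheticTruth(
        tah_ids=set(TAH_IDS),
        tf_edges=tf_edges,
        se_intervals=[GenomicInterval(CHROM, 2500, 7300)],
        se_assoc={"c01", "c02", "c03", "c04"},
        te_assoc={"c05", "c06", "c07", "c08", "c09", "c10"},
        contact_ids={"c01"},
        responsive_ids=responsive,
        lead_tf="TF_A",
        probe_map=probe_map,
        decoy_probes={"p_decoy"},
        ambiguous_probes=set(),
        planted_intensities=None,
        circ_ratio={},
    )
    return SyntheticDataset(
        config=config,
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
        control_matrix=ctrl,
        knockdown_matrix=kd,
        truth=truth,
    )


def expected_expression() -> pd.DataFrame:
    """Hand-computed expression/activity table for the fixture.

    RPM = junction reads (10^6 total reads); RPKM = RPM/112×1000;
    host RPKM = body reads / 13.5 (10^9·m / (10^6 · 13500));
    RPKM_ss = 10 × promoter peak height (1 kb peak inside the ±1 kb
    window, read length 50, 10^6 ChIP reads).
    """
    rows = []
    gene_info = {gid: (m, h) for gid, _, m, h in _GENE_SPEC}
    for cid, host, _, _, j, h in _CIRC_SPEC:
        m, hg = gene_info[host]
        rows.append(
            {
                "circ_id": cid,
                "rpm": float(j),
                "rpkm": j / 112 * 1000,
                "host_rpkm": m / 13.5,
                "circ_ss": 10.0 * h,
                "host_ss": 10.0 * hg,
                "is_tah": cid in TAH_IDS,
            }
        )
    return pd.DataFrame(rows)
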