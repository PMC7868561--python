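"""High-level runners wiring dataset objects through the analysis stages.

These helpers operate on in-memory objects (catalogs, count dicts, signal
tracks) and are shared by the CLI, the test suite and the acceptance
script.  Each mirrors one stage of the analysis: expression scoring,
promoter activity, TAH classification, and the knockdown enrichment
experiment.
"""

from __future__ import annotations

import numpy as np

from . import classify as _classify
from . import quantify as q
from . import stats as _stats
from .io import CircRNA, Gene, SignalTrack


def expression_tables(
    circs: list[CircRNA],
    genes: list[Gene],
    junction_reads: dict[str, float],
    body_reads: dict[str, float],
    total_rna_reads: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-circRNA back-splice RPKM and per-circRNA host RPKM_body.

    Host expression is the read-density RPKM over the host gene span;
    circRNA expression is the junction RPM scaled by the effective
    junction-detection length.
    """
    gene_map = {g.id: g for g in genes}
    circ_rpkm: dict[str, float] = {}
    host_rpkm: dict[str, float] = {}
    for c in circs:
        if c.host_gene is None or c.host_gene not in gene_map:
            continue
        g = gene_map[c.host_gene]
        rpm = q.rpm_backsplice(junction_reads.get(c.id, 0), total_rna_reads)
        circ_rpkm[c.id] = q.rpkm_backsplice(rpm)
        host_rpkm[c.id] = q.rpkm_body(
            body_reads.get(g.id, 0), total_rna_reads, g.end - g.start
        )
    return circ_rpkm, host_rpkm


def activity_tables(
    circs: list[CircRNA],
    genes: list[Gene],
    k27_track: SignalTrack,
    read_length: float = q.DEFAULT_READ_LENGTH,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-circRNA promoter activity (RPKM_ss) at the circRNA TSS and at
    its host's TSS."""
    gene_map = {g.id: g for g in genes}
    circ_act: dict[str, float] = {}
    host_act: dict[str, float] = {}
    for c in circs:
        if c.host_gene is None or c.host_gene not in gene_map:
            continue
        g = gene_map[c.host_gene]
        circ_act[c.id] = q.rpkm_ss(k27_track, c.chrom, c.tss, read_length)
        host_act[c.id] = q.rpkm_ss(k27_track, g.chrom, g.tss, read_length)
    return circ_act, host_act


def classify_dataset(dataset) -> tuple[list, dict]:
    """Run the full TAH classification on a synthetic dataset object."""
    circ_rpkm, host_rpkm = expression_tables(
        dataset.circs,
        dataset.genes,
        dataset.junction_reads,
        dataset.body_reads,
        dataset.config.total_rna_reads,
    )
    circ_act, host_act = activity_tables(
        dataset.circs,
        dataset.genes,
        dataset.k27_track,
        dataset.config.read_length,
    )
    return _classify.classify_tah(circ_rpkm, host_rpkm, circ_act, host_act)


def knockdown_experiment(
    dataset,
    draws: int = 20_000,
    gsea_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """The TF-knockdown enrichment experiment on a synthetic dataset.

    Replicates the analysis chain around a silenced master TF: (1) filter
    circRNAs down-regulated after knockdown; (2) test whether the TF-bound
    TAH-circRNAs are over-represented among them, by exact hypergeometric
    tail and by the 20,000-draw permutation null; (3) preranked GSEA of the
    bound TAH set in the knockdown-vs-control t ranking of circRNAs, and of
    the corresponding host-gene set in the gene ranking.
    """
    truth = dataset.truth
    cfg = dataset.config
    circ_ids = [c.id for c in dataset.circs]
    gene_ids = [g.id for g in dataset.genes]
    host_of = {c.id: c.host_gene for c in dataset.circs}

    ctrl = dataset.control_matrix
    kd = dataset.knockdown_matrix
    down = _stats.down_regulated_filter(
        kd.loc[circ_ids].to_numpy(), ctrl.loc[circ_ids].to_numpy(), circ_ids
    )
    cell = cfg.cell_lines[0]
    bound_tah = {
        target
        for (cl, tf, target, kind) in truth.tf_edges
        if cl == cell and tf == truth.lead_tf and kind == "circRNA"
        and target in truth.tah_ids
    }
    overlap = len(down & bound_tah)
    hyper = _stats.hypergeometric_overlap(
        len(circ_ids), len(down), len(bound_tah), overlap
    )
    perm = _stats.permutation_overlap(
        circ_ids, bound_tah, down, draws=draws, seed=seed
    )

    ranked_c = _stats.rank_by_tstat(
        ctrl.loc[circ_ids].to_numpy(), kd.loc[circ_ids].to_numpy(), circ_ids
    )
    gsea_circ = _stats.gsea_preranked(
        ranked_c["feature_id"], ranked_c["t"].to_numpy(), bound_tah,
        permutations=gsea_permutations, seed=seed,
    )
    host_set = {host_of[cid] for cid in bound_tah if host_of[cid] is not None}
    ranked_g = _stats.rank_by_tstat(
        ctrl.loc[gene_ids].to_numpy(), kd.loc[gene_ids].to_numpy(), gene_ids
    )
    gsea_host = _stats.gsea_preranked(
        ranked_g["feature_id"], ranked_g["t"].to_numpy(), host_set,
        permutations=gsea_permutations, seed=seed,
    )
    return {
        "n_down": len(down),
        "n_bound_tah": len(bound_tah),
        "overlap": overlap,
        "down_set": down,
        "bound_tah": bound_tah,
        "hypergeom_p": hyper.p_value,
        "permutation_p": perm.p_value,
        "gsea_circ_es": gsea_circ.es,
        "gsea_circ_p": gsea_circ.p_value,
        "gsea_host_es": gsea_host.es,
        "gsea_host_p": gsea_host.p_value,
    }
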