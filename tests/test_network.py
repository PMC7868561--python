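import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from circtah import network as nw
from circtah.io import CircRNA, Gene, GenomicInterval, PeakSet


def _circ(tss, strand="+", cid="c1"):
    if strand == "+":
        return CircRNA(cid, "chr1", tss, tss + 900, strand, "g1")
    return CircRNA(cid, "chr1", tss - 900, tss, strand, "g1")


class TestBuildNetwork:
    def test_one_bp_overlap_makes_edge(self):
        peaks = {("TF1", "CL"): PeakSet([GenomicInterval("chr1", 3000, 3100)])}
        edges = nw.build_network(peaks, [_circ(5000)], [])
        assert len(edges) == 1
        assert tuple(edges.iloc[0]) == ("TF1", "c1", "circRNA", "CL")

    def test_half_open_boundary_excluded(self):
        # window [3000, 6000): a peak ending exactly at 3000 misses it
        peaks = {("TF1", "CL"): PeakSet([GenomicInterval("chr1", 2999, 3000)])}
        edges = nw.build_network(peaks, [_circ(5000)], [])
        assert edges.empty

    def test_replicate_peaks_deduplicate(self):
        peaks = {
            ("TF1", "CL"): PeakSet(
                [
                    GenomicInterval("chr1", 3000, 3100),
                    GenomicInterval("chr1", 4000, 4100),
                ]
            )
        }
        edges = nw.build_network(peaks, [_circ(5000)], [])
        assert len(edges) == 1

    def test_window_enlargement_never_removes_edges(self, ds_default):
        narrow = nw.build_network(
            ds_default.tf_peaks, ds_default.circs, ds_default.genes,
            convention="expression_window",
        )
        wide = nw.build_network(
            ds_default.tf_peaks, ds_default.circs, ds_default.genes,
            convention="tf_window",
        )
        narrow_set = set(map(tuple, narrow.to_numpy()))
        wide_set = set(map(tuple, wide.to_numpy()))
        assert narrow_set <= wide_set

    def test_planted_edges_recovered_exactly(self, ds_noisefree):
        edges = nw.build_network(
            ds_noisefree.tf_peaks, ds_noisefree.circs, ds_noisefree.genes
        )
        found = {
            (row.cell_line, row.tf, row.target, row.kind)
            for row in edges.itertuples()
        }
        assert found == ds_noisefree.truth.tf_edges


class TestDegreeDistribution:
    def test_power_law_exponent_recovered(self):
        rng = np.random.default_rng(0)
        ks = np.arange(1, 21)
        probs = ks ** -2.0
        probs = probs / probs.sum()
        degrees = rng.choice(ks, size=5000, p=probs)
        rows = []
        for i, k in enumerate(degrees):
            rows.extend(
                {"tf": f"TF{j}", "target": f"t{i}", "kind": "circRNA",
                 "cell_line": "CL"}
                for j in range(k)
            )
        fit = nw.degree_distribution(pd.DataFrame(rows))
        assert abs(fit.exponent - 2.0) < 0.3
        assert fit.r_squared > 0.9

    def test_all_equal_degrees_flagged_degenerate(self):
        rows = [
            {"tf": "TF1", "target": f"t{i}", "kind": "circRNA", "cell_line": "CL"}
            for i in range(12)
        ]
        fit = nw.degree_distribution(pd.DataFrame(rows))
        assert fit.degenerate

    def test_isolated_targets_in_histogram_not_fit(self):
        rows = [
            {"tf": f"TF{j}", "target": f"t{i}", "kind": "circRNA", "cell_line": "CL"}
            for i in range(12)
            for j in range(1 + i % 3)
        ]
        base = nw.degree_distribution(pd.DataFrame(rows))
        with_iso = nw.degree_distribution(
            pd.DataFrame(rows), all_targets=[f"t{i}" for i in range(15)]
        )
        assert with_iso.histogram[0] == 3
        assert with_iso.exponent == base.exponent


class TestSharedPartition:
    @pytest.mark.parametrize(
        "circ_tfs,host_tfs,label",
        [
            ({"A", "B"}, {"A", "B"}, "all"),
            ({"A", "B"}, {"B", "C"}, "part"),
            ({"A"}, {"B"}, "none"),
            (set(), {"B"}, "no_tf"),
        ],
    )
    def test_three_way_labels(self, circ_tfs, host_tfs, label):
        circ_edges = pd.DataFrame(
            [{"tf": t, "target": "c1", "kind": "circRNA", "cell_line": "CL"}
             for t in circ_tfs]
        , columns=["tf", "target", "kind", "cell_line"])
        gene_edges = pd.DataFrame(
            [{"tf": t, "target": "g1", "kind": "gene", "cell_line": "CL"}
             for t in host_tfs]
        , columns=["tf", "target", "kind", "cell_line"])
        out = nw.shared_tf_partition(circ_edges, gene_edges, {"c1": "g1"})
        assert out.loc[0, "label"] == label


class TestCellSpecificity:
    def test_identical_peaksets_fill_top_bin(self, ds_noisefree):
        peaks = {("TF1", cl): ds_noisefree.k27_peaks for cl in ("A", "B", "C")}
        edges = nw.build_network(peaks, ds_noisefree.circs, ds_noisefree.genes)
        hist = nw.cell_specificity_distribution(edges)
        assert hist[1] == 0 and hist[2] == 0
        assert hist[3] > 0

    def test_independent_binding_matches_binomial(self, ds_multiline):
        edges = nw.build_network(
            ds_multiline.tf_peaks, ds_multiline.circs, ds_multiline.genes
        )
        gene_edges = edges[edges.kind == "gene"]
        hist = nw.cell_specificity_distribution(gene_edges)
        K, p = 4, ds_multiline.config.p_bind_gene
        # lead TF binds at a boosted rate; restrict to the uniform TFs
        uniform = gene_edges[gene_edges.tf != ds_multiline.truth.lead_tf]
        hist = nw.cell_specificity_distribution(uniform)
        total = sum(hist.values())
        pk = np.array([sps.binom.pmf(k, K, p) for k in range(1, K + 1)])
        pk = pk / pk.sum()
        obs = np.array([hist[k] for k in range(1, K + 1)])
        chi2 = sps.chisquare(obs, pk * total)
        assert chi2.pvalue > 0.01

    def test_single_cell_line_rejected(self):
        edges = pd.DataFrame(
            [{"tf": "TF1", "target": "c1", "kind": "circRNA", "cell_line": "CL"}]
        )
        with pytest.raises(ValueError):
            nw.cell_specificity_distribution(edges)


class TestRankTfs:
    def test_boosted_tf_ranks_first(self, ds_large):
        edges = nw.build_network(
            ds_large.tf_peaks, ds_large.circs, ds_large.genes
        )
        circ_rank, gene_rank, rho = nw.rank_tfs(edges)
        assert circ_rank.index[0] == ds_large.truth.lead_tf
        assert gene_rank.index[0] == ds_large.truth.lead_tf
        assert rho > 0

    def test_target_relabelling_preserves_ranking(self, ds_default):
        edges = nw.build_network(
            ds_default.tf_peaks, ds_default.circs, ds_default.genes
        )
        relabel = {t: f"x{i}" for i, t in enumerate(edges["target"].unique())}
        permuted = edges.assign(target=edges["target"].map(relabel))
        a, _, _ = nw.rank_tfs(edges)
        b, _, _ = nw.rank_tfs(permuted)
        assert list(a.index) == list(b.index)
        assert list(a.values) == list(b.values)

    def test_edge_count_consistency(self, ds_default):
        edges = nw.build_network(
            ds_default.tf_peaks, ds_default.circs, ds_default.genes
        )
        per_tf = edges.groupby("tf").size().sum()
        assert per_tf == len(edges)
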