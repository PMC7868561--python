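import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from circtah import superenhancer as se
from circtah.io import CircRNA, GenomicInterval, PeakSet, SignalTrack


def _peaks(spans, chrom="chr1"):
    return PeakSet([GenomicInterval(chrom, a, b) for a, b in spans])


def _brute_force_stitch(spans, tss, stitch_bp, excl):
    """Independent oracle: drop TSS-contained peaks, merge by pairwise scan."""
    kept = [
        (a, b)
        for a, b in sorted(spans)
        if not any(a >= t - excl and b <= t + excl for t in tss)
    ]
    merged = []
    for a, b in kept:
        if merged and a - merged[-1][1] < stitch_bp:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


class TestStitch:
    def test_gap_below_threshold_merges(self):
        out = se.stitch(_peaks([(0, 1000), (5000, 6000)]), [])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 6000)
        assert len(out[0].constituents) == 2

    def test_gap_above_threshold_stays_split(self):
        out = se.stitch(_peaks([(0, 1000), (21_000, 22_000)]), [])
        assert len(out) == 2

    def test_tss_contained_peak_removed(self):
        out = se.stitch(
            _peaks([(4900, 5100), (30_000, 31_000)]), [("chr1", 5000)]
        )
        assert len(out) == 1
        assert out[0].interval.start == 30_000

    def test_nonpositive_stitch_rejected(self):
        with pytest.raises(ValueError):
            se.stitch(_peaks([(0, 10)]), [], stitch_bp=0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(1, 15)
            starts = np.sort(rng.integers(0, 200_000, size=n))
            lengths = rng.integers(100, 5000, size=n)
            spans = [(int(s), int(s + l)) for s, l in zip(starts, lengths)]
            # drop overlapping spans to keep inputs valid peak calls
            clean = []
            for a, b in spans:
                if not clean or a >= clean[-1][1]:
                    clean.append((a, b))
            tss = [int(t) for t in rng.integers(0, 200_000, size=3)]
            stitch_bp = int(rng.integers(1000, 20_000))
            got = se.stitch(
                _peaks(clean), [("chr1", t) for t in tss], stitch_bp, 2000
            )
            want = _brute_force_stitch(clean, tss, stitch_bp, 2000)
            assert [(r.interval.start, r.interval.end) for r in got] == want

    def test_larger_stitch_never_more_regions(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, 500_000, size=40))
        spans = []
        for s in starts:
            if not spans or s >= spans[-1][1]:
                spans.append((int(s), int(s) + 500))
        counts = [
            len(se.stitch(_peaks(spans), [], bp))
            for bp in (1000, 5000, 12_500, 50_000)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def _uniform_track(height, spans, total=1e6, chrom="chr1"):
    return SignalTrack.from_records(
        [(chrom, a, b, height) for a, b in spans], total
    )


class TestRankAndCut:
    def _regions(self, spans):
        return [
            se.StitchedEnhancer(
                GenomicInterval("chr1", a, b),
                constituents=[GenomicInterval("chr1", a, b)],
            )
            for a, b in spans
        ]

    def test_single_outlier_is_the_only_super(self):
        spans = [(i * 10_000, i * 10_000 + 1000) for i in range(5)]
        sample = SignalTrack.from_records(
            [("chr1", a, b, 100.0 if i == 4 else 1.0)
             for i, (a, b) in enumerate(spans)],
            1e6,
        )
        ranked = se.rank_and_cut(self._regions(spans), sample)
        supers = [r for r in ranked if r.is_super]
        assert len(supers) == 1
        assert supers[0].interval.start == 40_000

    def test_input_equal_to_sample_floors_signals(self):
        spans = [(0, 1000), (10_000, 11_000), (20_000, 21_000)]
        track = _uniform_track(2.0, spans)
        ranked = se.rank_and_cut(self._regions(spans), track, track)
        assert all(r.signal == 0 for r in ranked)
        assert not any(r.is_super for r in ranked)

    def test_se_te_partition_separates_signals(self):
        rng = np.random.default_rng(2)
        spans = [(i * 10_000, i * 10_000 + 1000) for i in range(30)]
        sample = SignalTrack.from_records(
            [("chr1", a, b, float(rng.uniform(0.5, 5)))
             for a, b in spans],
            1e6,
        )
        ranked = se.rank_and_cut(self._regions(spans), sample)
        s_sig = [r.signal for r in ranked if r.is_super]
        t_sig = [r.signal for r in ranked if not r.is_super]
        if s_sig and t_sig:
            assert min(s_sig) > max(t_sig)

    def test_cutoff_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            s = np.sort(rng.lognormal(0, 1.5, size=int(rng.integers(3, 40))))
            if s[-1] == s[0]:
                continue
            x = np.arange(len(s)) / (len(s) - 1)
            y = (s - s[0]) / (s[-1] - s[0])
            # brute force: try every index as the slope-1 support point
            best = min(range(len(s)), key=lambda i: y[i] - x[i])
            assert se.hockey_stick_cutoff(s) == s[best]

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            se.rank_and_cut(self._regions([(0, 10), (20, 30)]),
                            _uniform_track(1.0, [(0, 30)]))


class TestAssignment:
    def _enh(self, a, b, is_super, signal):
        e = se.StitchedEnhancer(GenomicInterval("chr1", a, b))
        e.is_super, e.signal = is_super, signal
        return e

    def test_tss_within_window_assigns(self):
        enh = [self._enh(0, 5000, True, 100.0)]
        c = CircRNA("c1", "chr1", 15_000, 16_000, "+", "g")
        out = se.assign_circrnas(enh, [c])
        assert out.loc[0, "label"] == "SE"

    def test_out_of_reach_is_none(self):
        enh = [self._enh(0, 5000, True, 100.0)]
        c = CircRNA("c1", "chr1", 100_000, 101_000, "+", "g")
        out = se.assign_circrnas(enh, [c])
        assert out.loc[0, "label"] == "none"

    def test_equidistant_tie_prefers_higher_signal(self):
        enh = [self._enh(0, 1000, False, 10.0), self._enh(21_000, 22_000, True, 99.0)]
        c = CircRNA("c1", "chr1", 11_000, 11_500, "+", "g")  # TSS 10 kb from both
        out = se.assign_circrnas(enh, [c])
        assert out.loc[0, "label"] == "SE"

    def test_truth_labels_recovered(self, ds_noisefree):
        ds = ds_noisefree
        tss = [(g.chrom, g.tss) for g in ds.genes] + [
            (c.chrom, c.tss) for c in ds.circs
        ]
        regions = se.stitch(ds.k27_peaks, tss)
        ranked = se.rank_and_cut(regions, ds.k27_track, ds.input_track)
        labels = se.assign_circrnas(ranked, ds.circs)
        assert set(labels.loc[labels.label == "SE", "circ_id"]) == ds.truth.se_assoc
        assert set(labels.loc[labels.label == "TE", "circ_id"]) == ds.truth.te_assoc


class TestCompareSeTe:
    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 200
        for _ in range(reps):
            vals = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=60))}
            labels = pd.DataFrame(
                {"circ_id": list(vals), "label": ["SE"] * 30 + ["TE"] * 30}
            )
            if se.compare_se_te(labels, vals)["p_value"] < 0.05:
                rejections += 1
        assert abs(rejections / reps - 0.05) < 0.03

    def test_single_member_class_skips_test(self):
        labels = pd.DataFrame(
            {"circ_id": ["a", "b", "c"], "label": ["SE", "TE", "TE"]}
        )
        out = se.compare_se_te(labels, {"a": 1.0, "b": 2.0, "c": 3.0})
        assert np.isnan(out["p_value"])
        assert out["mean_se"] == 1.0
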