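"""Bin scoring, maximal-scoring-segment search and the broad-domain caller."""

import numpy as np
import pytest

from sammyseq import (
    Genome,
    IntervalSet,
    bin_and_normalize,
    broad_peaks,
    call_domains,
    calls_to_intervals,
    log_ratio_track,
    maximal_segments,
    score_bins,
)
from sammyseq.domains import BinScoreVector, _ruzzo_tompa, max_segment_score
from sammyseq.synthetic import simulate_fraction_reads
from sammyseq.tracks import BinnedTrack


def make_track(values, bin_size=10):
    g = Genome(("c",), (len(values) * bin_size,))
    return BinnedTrack(g, bin_size, {"c": np.asarray(values, dtype=float)},
                       library_size=int(max(np.sum(np.abs(values)), 1)))


def score_vector(values, gap_penalty):
    """BinScoreVector straight from raw scores (for segment-search tests)."""
    arr = np.asarray(values, dtype=float)
    g = Genome(("c",), (len(arr) * 10,))
    return BinScoreVector(
        g, 10, {"c": arr}, {"c": arr != 0},
        {"c": np.zeros(len(arr), dtype=bool)}, gap_penalty, 0.0,
    )


def rt_oracle(x):
    """Recursive max-subarray decomposition (shortest-then-leftmost ties):
    the defining property of the maximal-scoring-subsequence set."""
    x = list(x)
    out = []

    def best(lo, hi):
        top, iv = 0.0, None
        for i in range(lo, hi):
            ssum = 0.0
            for j in range(i, hi):
                ssum += x[j]
                better = ssum > top + 1e-12
                tie_shorter = (abs(ssum - top) <= 1e-12 and iv is not None
                               and (j + 1 - i) < (iv[1] - iv[0]))
                if better or tie_shorter:
                    top, iv = ssum, (i, j + 1)
        return top, iv

    def rec(lo, hi):
        if lo >= hi:
            return
        sc, iv = best(lo, hi)
        if iv is None:
            return
        out.append((iv[0], iv[1], sc))
        rec(lo, iv[0])
        rec(iv[1], hi)

    rec(0, len(x))
    return sorted(out)


class TestScoreBins:
    def test_constant_input_no_enriched_bins(self):
        t = make_track([1.0] * 8)
        lr = log_ratio_track(t, t)
        sv = score_bins(lr, None, gap_penalty=10)
        assert (sv.scores["c"] <= 0).all()

    def test_median_split_example(self):
        lr = make_track([-1.0, -1.0, 2.0, 2.0])
        lr.normalization = "log2ratio"
        sv = score_bins(lr, None, gap_penalty=10, threshold_mode="median")
        assert list(sv.scores["c"]) == [-10.0, -10.0, 1.0, 1.0]
        assert sv.polarity_threshold == pytest.approx(0.5)

    def test_otsu_agrees_on_bimodal_example(self):
        lr = make_track([-1.0, -1.0, 2.0, 2.0])
        sv = score_bins(lr, None, gap_penalty=10, threshold_mode="otsu")
        assert list(sv.scores["c"]) == [-10.0, -10.0, 1.0, 1.0]

    def test_blacklist_bins_non_informative(self):
        lr = make_track([5.0, 5.0, -1.0, -1.0])
        bl = IntervalSet.from_tuples([("c", 0, 10)])
        sv = score_bins(lr, bl, gap_penalty=10)
        assert sv.scores["c"][0] == 0.0
        assert not sv.informative["c"][0]
        # informative=false <=> score = 0
        assert np.array_equal(sv.informative["c"], sv.scores["c"] != 0)

    def test_zero_reference_bins_non_informative(self):
        lr = make_track([1.0, 2.0, 3.0, 4.0])
        ref = make_track([1.0, 0.0, 2.0, 3.0])
        sv = score_bins(lr, None, gap_penalty=5, reference=ref)
        assert sv.scores["c"][1] == 0.0

    def test_all_non_informative_rejected(self):
        lr = make_track([1.0, 2.0])
        bl = IntervalSet.from_tuples([("c", 0, 20)])
        with pytest.raises(ValueError, match="non-informative"):
            score_bins(lr, bl, gap_penalty=5)


class TestMaximalSegments:
    def test_all_positive_single_segment(self):
        segs = maximal_segments(score_vector([1.0] * 6, 2))
        assert len(segs) == 1
        iv, sc = segs[0]
        assert (iv.start, iv.end, sc) == (0, 60, 6.0)

    def test_worked_example(self):
        segs = maximal_segments(score_vector([1, 1, -2, 1, 1, 1], 2))
        got = [(iv.start // 10, iv.end // 10, sc) for iv, sc in segs]
        assert got == [(0, 2, 2.0), (3, 6, 3.0)]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            G = float(rng.choice([1, 2, 5]))
            n = int(rng.integers(1, 26))
            x = rng.choice([1.0, -G, 0.0], size=n, p=[0.45, 0.45, 0.1])
            got = sorted(_ruzzo_tompa(x))
            assert got == rt_oracle(x), f"x={list(x)} G={G}"

    def test_no_positive_bins_empty(self):
        assert maximal_segments(score_vector([-2.0, -2.0], 2)) == []

    def test_segments_do_not_cross_blacklist_blocks(self):
        sv = score_vector([1, 1, 1, 1], 2)
        sv.blocked["c"][2] = True
        sv.scores["c"][2] = 0.0
        sv.informative["c"][2] = False
        segs = maximal_segments(sv)
        got = [(iv.start // 10, iv.end // 10) for iv, _ in segs]
        assert got == [(0, 2), (3, 4)]

    def test_kadane_agrees_with_segment_max(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.choice([1.0, -2.0, 0.0], size=30)
            segs = _ruzzo_tompa(x)
            best = max((sc for *_, sc in segs), default=0.0)
            assert max_segment_score(x) == pytest.approx(best)


class TestCaller:
    def test_target_equals_reference_no_calls(self, toy_genome):
        rng = np.random.default_rng(0)
        reads = [("chr1", int(m)) for m in rng.integers(0, 30_000_000, 50_000)]
        calls = call_domains(reads, reads, toy_genome, 100_000,
                             n_permutations=200, seed=1)
        assert calls == []

    def test_recovery_of_planted_domains(self, default_arch, default_calls,
                                         default_call_set):
        from sammyseq import jaccard

        assert jaccard(default_call_set, default_arch.closed_domains) >= 0.9
        for d in default_arch.closed_domains:
            assert default_call_set.overlap_bp(d.chrom, d.start, d.end) > 0

    def test_calls_avoid_blacklist_and_are_bin_aligned(self, default_arch,
                                                       default_reads):
        bl = IntervalSet.from_tuples([
            (iv.chrom, iv.start + iv.length // 2 - 20_000,
             iv.start + iv.length // 2 + 20_000)
            for iv in default_arch.closed_domains
        ][:3])
        calls = call_domains(default_reads["S4"], default_reads["S2"],
                             default_arch.genome, 10_000, blacklist=bl,
                             n_permutations=300, seed=5)
        cs = calls_to_intervals(calls)
        assert len(cs)
        assert cs.intersect(bl).total_bp() == 0
        for c in calls:
            assert c.interval.start % 10_000 == 0
            assert (c.interval.end % 10_000 == 0
                    or c.interval.end == default_arch.genome.length(c.interval.chrom))
            assert c.informative_fraction >= 0.98

    def test_gap_penalty_monotonicity(self, default_arch):
        r4 = simulate_fraction_reads(default_arch, "S4", 200_000, seed=41)
        r2 = simulate_fraction_reads(default_arch, "S2", 200_000, seed=42)
        t4 = bin_and_normalize(r4, default_arch.genome, 10_000)
        t2 = bin_and_normalize(r2, default_arch.genome, 10_000)
        lr = log_ratio_track(t4, t2)
        called_bp = []
        for G in (1.0, 5.0, 25.0, 100.0):
            sv = score_bins(lr, None, gap_penalty=G, reference=t2)
            segs = maximal_segments(sv)
            called_bp.append(sum(iv.length for iv, _ in segs))
        assert all(a >= b for a, b in zip(called_bp, called_bp[1:]))

    def test_few_permutations_warns(self, default_arch, default_reads):
        with pytest.warns(UserWarning, match="permutations"):
            call_domains(default_reads["S4"].iloc[:20_000],
                         default_reads["S2"].iloc[:20_000],
                         default_arch.genome, 100_000, n_permutations=50,
                         seed=2)


def test_presets_cover_the_four_assays():
    from sammyseq import PRESETS

    assert set(PRESETS) == {"sammy", "h3k9me3", "laminAC", "laminB1"}
    assert PRESETS["h3k9me3"]["fdr"] == 0.1
    assert PRESETS["sammy"]["gap_penalty"] == 25.0
    assert PRESETS["laminB1"]["gap_penalty"] == 5.0


class TestBroadPeaks:
    def test_concentrated_reads_single_window(self):
        g = Genome(("c",), (100_000,))
        reads = [("c", 5_100)] * 200 + [("c", i * 97) for i in range(1000)]
        peaks = broad_peaks(reads, g, window=2000, z_threshold=3)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (4000, 6000)

    def test_adjacent_hot_windows_merge(self):
        g = Genome(("c",), (100_000,))
        reads = ([("c", 4_500)] * 150 + [("c", 6_500)] * 150
                 + [("c", i * 97) for i in range(1000)])
        peaks = broad_peaks(reads, g, window=2000, z_threshold=3)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (4000, 8000)

    def test_uniform_significant_fraction_small(self):
        g = Genome(("c",), (10_000_000,))
        rng = np.random.default_rng(6)
        # mean 40 reads per 2-kb window
        reads = [("c", int(m)) for m in rng.integers(0, 10_000_000, 200_000)]
        peaks = broad_peaks(reads, g, window=2000, z_threshold=3)
        sig_windows = sum(iv.length // 2000 for iv in peaks)
        assert sig_windows / 5000 <= 0.01

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            broad_peaks([], Genome(("c",), (10_000,)))
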