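"""Generator contracts: determinism, planted contrast, state painting,
transcript nulls, and nucleus ground truth."""

import numpy as np
import pytest
from scipy import stats

from sammyseq import (
    bin_and_normalize,
    make_architecture,
    paint_chromatin_states,
    simulate_fraction_reads,
    simulate_mark_track,
    simulate_nuclei,
    simulate_transcript_table,
)
from sammyseq import IntervalSet
from sammyseq.synthetic import STATE_LABELS


def in_domain_mask(domains, frame):
    """Vectorized membership of read midpoints in a flat interval set."""
    out = np.zeros(len(frame), dtype=bool)
    by = domains.merge().by_chrom()
    for chrom, arr in by.items():
        sel = (frame["chrom"] == chrom).to_numpy()
        mids = frame["midpoint"].to_numpy()[sel]
        idx = np.searchsorted(arr[:, 0], mids, side="right") - 1
        ok = (idx >= 0) & (mids < arr[np.clip(idx, 0, None), 1])
        out[np.flatnonzero(sel)[ok]] = True
    return out


class TestArchitecture:
    def test_zero_domains(self):
        arch = make_architecture({"c": 10_000_000}, 0, (1_000_000, 2_000_000),
                                 3.0, seed=1)
        assert len(arch.closed_domains) == 0

    def test_placement_constraints(self):
        arch = make_architecture({"a": 30_000_000, "b": 30_000_000}, 10,
                                 (1_000_000, 5_000_000), 3.0, seed=7)
        assert len(arch.closed_domains) == 10
        total = arch.closed_domains.total_bp()
        assert 10_000_000 <= total <= 50_000_000
        # disjoint: merged bp equals summed bp
        assert sum(iv.length for iv in arch.closed_domains) == total

    def test_deterministic(self):
        kw = dict(chrom_sizes={"a": 30_000_000}, n_domains=5,
                  size_range=(500_000, 2_000_000), enrichment_factor=3.0, seed=7)
        assert (list(make_architecture(**kw).closed_domains)
                == list(make_architecture(**kw).closed_domains))

    def test_impossible_placement_fails_loudly(self):
        with pytest.raises(RuntimeError, match="place"):
            make_architecture({"c": 10_000_000}, 10, (4_000_000, 5_000_000),
                              3.0, seed=0)

    def test_size_range_must_fit(self):
        with pytest.raises(ValueError):
            make_architecture({"c": 1_000_000}, 1, (2_000_000, 3_000_000),
                              3.0, seed=0)


class TestFractionReads:
    def test_uniform_at_factor_one(self):
        arch = make_architecture({"c": 10_000_000}, 3, (500_000, 1_000_000),
                                 1.0, seed=2)
        reads = simulate_fraction_reads(arch, "S4", 100_000, seed=3)
        counts = bin_and_normalize(reads, arch.genome, 100_000).data["c"]
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.01

    @pytest.mark.parametrize("fraction,lo,hi", [
        ("S4", 2.5, 3.5),
        ("S2", 1 / 3.5, 1 / 2.5),
    ])
    def test_in_out_density_ratio(self, default_arch, fraction, lo, hi):
        reads = simulate_fraction_reads(default_arch, fraction, 1_000_000,
                                        seed=11)
        track = bin_and_normalize(reads, default_arch.genome, 10_000)
        dom = default_arch.closed_domains
        inside, outside = [], []
        for chrom, arr in track.data.items():
            for i, v in enumerate(arr):
                frac = dom.overlap_bp(chrom, i * 10_000, (i + 1) * 10_000) / 10_000
                if frac == 1.0:
                    inside.append(v)
                elif frac == 0.0:
                    outside.append(v)
        ratio = np.mean(inside) / np.mean(outside)
        assert lo <= ratio <= hi

    def test_s4_s2_contrast_is_factor_squared(self, default_arch):
        """Generator-level invariant: in-domain S4/S2 density ratio ~ factor^2."""
        n = 1_000_000
        r4 = simulate_fraction_reads(default_arch, "S4", n, seed=21)
        r2 = simulate_fraction_reads(default_arch, "S2", n, seed=22)
        dom = default_arch.closed_domains
        f4 = in_domain_mask(dom, r4).mean()
        f2 = in_domain_mask(dom, r2).mean()
        dens_ratio = (f4 / (1 - f4)) / (f2 / (1 - f2))
        expected = default_arch.enrichment_factor ** 2
        # 3 binomial standard errors propagated through the odds ratio
        se = 3 * dens_ratio * np.sqrt(
            (1 / (n * f4 * (1 - f4))) + (1 / (n * f2 * (1 - f2))))
        assert abs(dens_ratio - expected) < se

    def test_deterministic(self, default_arch):
        a = simulate_fraction_reads(default_arch, "S3", 10_000, seed=5)
        b = simulate_fraction_reads(default_arch, "S3", 10_000, seed=5)
        assert a.equals(b)

    def test_unknown_fraction(self, default_arch):
        with pytest.raises(ValueError, match="fraction"):
            simulate_fraction_reads(default_arch, "S9", 100, seed=0)

    def test_disrupted_flattens_contrast(self, default_arch):
        from dataclasses import replace

        disrupted = replace(default_arch, condition_label="disrupted")
        dom = default_arch.closed_domains
        frac_in = [
            in_domain_mask(dom, simulate_fraction_reads(arch, "S4", 50_000,
                                                        seed=9)).mean()
            for arch in (default_arch, disrupted)
        ]
        assert frac_in[1] < frac_in[0]


class TestMarkTrack:
    def test_noiseless_square_wave(self, default_arch):
        t = simulate_mark_track(default_arch, +1, 0.0, 10_000, seed=1)
        vals = t.values()
        assert set(np.unique(vals)) <= {-1.0, 1.0}
        in_bp = default_arch.closed_domains.total_bp()
        assert abs((vals == 1.0).mean() - in_bp / default_arch.genome.total_bp) < 0.01

    def test_polarity_negation(self, default_arch):
        p = simulate_mark_track(default_arch, +1, 0.0, 10_000, seed=1)
        m = simulate_mark_track(default_arch, -1, 0.0, 10_000, seed=1)
        r = np.corrcoef(p.values(), m.values())[0, 1]
        assert r == pytest.approx(-1.0)

    def test_invalid_args(self, default_arch):
        with pytest.raises(ValueError):
            simulate_mark_track(default_arch, +1, -0.1, 10_000, seed=1)
        with pytest.raises(ValueError):
            simulate_mark_track(default_arch, +1, 0.1, 0, seed=1)


class TestStatePainting:
    def test_partition_of_genome(self, default_arch):
        states = paint_chromatin_states(default_arch, seed=4)
        assert all(iv.name in STATE_LABELS for iv in states)
        # exact partition: total bp equals genome, and no overlaps
        assert sum(iv.length for iv in states) == default_arch.genome.total_bp
        assert states.total_bp() == default_arch.genome.total_bp

    def test_closed_domains_mostly_het_quies(self, default_arch):
        states = paint_chromatin_states(default_arch, seed=4)
        dom = default_arch.closed_domains
        hq = IntervalSet(
            iv for iv in states if iv.name in ("Het", "Quies")
        ).merge()
        assert dom.intersect(hq).total_bp() / dom.total_bp() >= 0.6

    def test_deterministic(self, default_arch):
        a = paint_chromatin_states(default_arch, seed=4)
        b = paint_chromatin_states(default_arch, seed=4)
        assert a == b


class TestTranscriptTable:
    def test_global_null_uniform(self, default_arch):
        states = paint_chromatin_states(default_arch, seed=4)
        txs = simulate_transcript_table(states, 5000, 1.0, seed=5)
        pvals = [t.p_value for t in txs]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bivalent_signal(self, default_arch):
        states = paint_chromatin_states(default_arch, seed=4)
        txs = simulate_transcript_table(states, 5000, 0.2, seed=6)
        from sammyseq import assign_chromatin_context

        assigned = assign_chromatin_context(txs, states)
        biv_p = [t.p_value for t in assigned if t.bivalent]
        nonbiv_p = [t.p_value for t in assigned if not t.bivalent]
        assert len(biv_p) >= 100
        assert np.median(biv_p) < 0.1
        assert stats.kstest(nonbiv_p, "uniform").pvalue > 0.01

    def test_effect_bounds(self, default_arch):
        states = paint_chromatin_states(default_arch, seed=4)
        with pytest.raises(ValueError):
            simulate_transcript_table(states, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_transcript_table(states, 10, 1.5, seed=0)


class TestNuclei:
    def test_zero_foci(self):
        sim = simulate_nuclei(3, 30, (0, 0), 0.5, 0.1, seed=1)
        assert sim.images.shape[0] == 3
        assert len(sim.foci) == 0

    def test_periphery_bias_one_clamps_proximity(self):
        sim = simulate_nuclei(10, 40, (3, 6), 1.0, 0.1, seed=2)
        assert (sim.foci["proximity"] <= 0.2).all()

    def test_physical_radius(self):
        sim = simulate_nuclei(2, 50, (1, 2), 0.5, 0.1, seed=3)
        assert (sim.nuclei["radius_um"] == 5.0).all()

    def test_deterministic(self):
        a = simulate_nuclei(2, 30, (2, 4), 0.5, 0.1, seed=9)
        b = simulate_nuclei(2, 30, (2, 4), 0.5, 0.1, seed=9)
        assert np.array_equal(a.images, b.images)
        assert a.foci.equals(b.foci)

    def test_radius_too_small(self):
        with pytest.raises(ValueError):
            simulate_nuclei(1, 5, (1, 2), 0.5, 0.1, seed=0)
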