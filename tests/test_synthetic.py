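"""Tests of the synthetic-data generators: determinism, distributional
targets, and wave geometry."""
import numpy as np
import pytest

from polwave import synthetic as syn
from polwave.models import GeneModel


class TestMakeGenes:
    def test_degenerate_length_law_gives_exact_lengths(self):
        genes = syn.make_genes(1, length_median=50_000, length_sigma=0.0, seed=0)
        assert len(genes) == 1
        assert genes[0].length == 50_000

    def test_same_seed_is_bit_identical(self):
        a = syn.make_genes(200, seed=1)
        b = syn.make_genes(200, seed=1)
        assert a == b

    def test_different_seeds_differ(self):
        assert syn.make_genes(50, seed=1) != syn.make_genes(50, seed=2)

    def test_median_length_near_target(self):
        genes = syn.make_genes(200, length_median=30_000, length_sigma=1.0, seed=3)
        med = np.median([g.length for g in genes])
        assert abs(med - 30_000) / 30_000 < 0.20

    def test_genes_do_not_overlap(self):
        genes = sorted(syn.make_genes(100, seed=4), key=lambda g: g.start)
        for g1, g2 in zip(genes, genes[1:]):
            assert g1.end <= g2.start

    def test_both_strands_present(self):
        strands = {g.strand for g in syn.make_genes(100, seed=5)}
        assert strands == {"+", "-"}

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            syn.make_genes(0)


class TestRatePresets:
    def test_preset_means(self, rng):
        assert abs(syn.draw_rates(syn.WT_RATE, 100_000, rng).mean() - 2450) < 30
        assert abs(syn.draw_rates(syn.SLOW_RATE, 100_000, rng).mean() - 1780) < 20
        assert np.all(syn.draw_rates(syn.WT_FRONT, 5, rng) == 2200.0)
        assert np.all(syn.draw_rates(syn.SLOW_FRONT, 5, rng) == 1780.0)

    def test_rates_strictly_positive(self, rng):
        for preset in syn.PRESETS.values():
            assert np.all(syn.draw_rates(preset, 1_000, rng) > 0)

    def test_slow_is_narrower_than_wt(self, rng):
        wt = syn.draw_rates(syn.WT_RATE, 50_000, rng)
        slow = syn.draw_rates(syn.SLOW_RATE, 50_000, rng)
        assert np.std(slow) / np.mean(slow) < np.std(wt) / np.mean(wt)

    def test_bad_mixture_weights_rejected(self):
        with pytest.raises(ValueError):
            syn.RatePreset("bad", "lognormal-mixture", mean=2000, sigma=0.3,
                           components=((0.6, 1500.0), (0.6, 3400.0)))


class TestWaveCoverage:
    def test_noise_free_front_at_v_times_t(self):
        profile = syn.expected_wave_profile(60_000, v=2_000, t=5, bin_size=500)
        nonzero = np.nonzero(profile > 1e-12)[0]
        # last labeled bin is [9500, 10000): front = v*t = 10 kb
        assert nonzero[-1] == 19

    def test_t0_signal_confined_to_promoter_zone(self):
        profile = syn.expected_wave_profile(60_000, v=3_000, t=0, bin_size=500)
        assert profile[:2].sum() > 0
        assert profile[2:].sum() == 0

    def test_front_truncated_at_gene_end(self):
        profile = syn.expected_wave_profile(5_000, v=2_000, t=15, bin_size=500)
        assert len(profile) == 10
        assert np.all(np.isfinite(profile)) and profile.sum() > 0

    def test_gene_shorter_than_one_bin_rejected(self):
        with pytest.raises(ValueError):
            syn.expected_wave_profile(400, v=2_000, t=5, bin_size=500)

    def test_small_bins_rejected(self):
        with pytest.raises(ValueError):
            syn.expected_wave_profile(60_000, v=2_000, t=5, bin_size=50)

    def test_poisson_total_matches_expectation(self):
        """Monte-Carlo total reads agree with the noise-free expectation."""
        gene = GeneModel("g1", "chr1", "+", 0, 60_000)
        design = syn.PulseDesign(harvest_times=(5.0,), depth=50.0)
        expected = syn.expected_wave_profile(60_000, 2_000, 5.0, depth=50.0).sum()
        totals = [
            syn.simulate_wave_coverage([gene], syn.RatePreset("c", "constant", 2_000),
                                       design, seed=s).profile("g1", 5.0).counts.sum()
            for s in range(500)
        ]
        assert abs(np.mean(totals) - expected) / expected < 0.05

    def test_expected_total_scales_linearly_with_depth(self):
        t1 = syn.expected_wave_profile(60_000, 2_000, 5.0, depth=10.0).sum()
        t5 = syn.expected_wave_profile(60_000, 2_000, 5.0, depth=50.0).sum()
        assert t5 == pytest.approx(5 * t1)

    def test_determinism(self):
        genes = syn.make_genes(5, seed=0)
        a = syn.simulate_wave_coverage(genes, syn.WT_RATE, seed=9)
        b = syn.simulate_wave_coverage(genes, syn.WT_RATE, seed=9)
        assert a.true_rates == b.true_rates
        for key in a.coverages:
            np.testing.assert_array_equal(a.coverages[key].counts, b.coverages[key].counts)


class TestQpcrSim:
    def test_signal_reaches_half_plateau_at_crossing_time(self):
        series, = syn.simulate_qpcr_timecourse(
            3.325, [133.0], list(range(0, 130, 10)), noise_sd=0.0)
        plateau = np.mean(series.values[-2:])
        first = series.times[np.nonzero(series.values >= 0.5 * plateau)[0][0]]
        assert first == 40.0  # crossing time d / v = 133 / 3.325 = 40 min

    def test_infinite_rate_limit_all_junctions_at_plateau(self):
        series = syn.simulate_qpcr_timecourse(1e9, [10.0, 100.0], [10, 20, 30])
        for s in series:
            assert np.all(s.values == 1.0)

    def test_same_seed_identical(self):
        a, = syn.simulate_qpcr_timecourse(2.0, [50.0], [0, 10, 20, 30], noise_sd=0.2, seed=4)
        b, = syn.simulate_qpcr_timecourse(2.0, [50.0], [0, 10, 20, 30], noise_sd=0.2, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_qpcr_timecourse(0.0, [50.0], [0, 10])


class TestJunctionCounts:
    def test_dpsi_recovery_from_binomial_sampling(self):
        """Mean empirical PSI difference tracks the generative dPSI."""
        events = syn.simulate_junction_counts(
            500, psi_base=50.0, dpsi_true=-40.0, depth=200, seed=11)
        diffs = []
        for ev in events:
            ia, ea = ev.counts("WT")
            ib, eb = ev.counts("slow")
            diffs.append(100 * ib / (ib + eb) - 100 * ia / (ia + ea))
        assert abs(np.mean(diffs) - (-40.0)) < 3.0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_junction_counts(10, depth=0)

    def test_infeasible_psi_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_junction_counts(10, psi_base=95.0, dpsi_true=20.0)

    def test_truth_labels_stored(self):
        events = syn.simulate_junction_counts(5, dpsi_true=20.0, seed=0)
        assert all(ev.true_dpsi == 20.0 for ev in events)

    def test_microexons_respect_length_cutoff(self):
        events = syn.simulate_junction_counts(300, seed=2)
        for ev in events:
            if ev.event_type == "MIC":
                assert ev.seg_end - ev.seg_start <= 27


class TestExpressionSim:
    def test_zero_effect_flags_nothing(self):
        genes = syn.make_genes(100, seed=0)
        effect = syn.LengthEffectPreset(p_short=0.0, p_long=0.0)
        records = syn.simulate_expression(genes, effect, seed=1)
        assert sum(r.true_down for r in records) == 0

    def test_certain_effect_flags_everything(self):
        genes = syn.make_genes(100, seed=0)
        effect = syn.LengthEffectPreset(p_short=1.0, p_long=1.0)
        records = syn.simulate_expression(genes, effect, seed=1)
        assert all(r.true_down for r in records)

    def test_down_fraction_matches_short_gene_anchor(self):
        genes = syn.make_genes(5_000, length_median=30_000, length_sigma=1.2, seed=2)
        records = syn.simulate_expression(genes, seed=3)
        sub = [r for r in records if 8_000 <= r.length <= 12_000]
        frac = np.mean([r.direction == "DOWN" for r in sub])
        assert abs(frac - 0.40) < 0.05

    def test_down_genes_have_negative_log2fc(self):
        genes = syn.make_genes(500, seed=4)
        for r in syn.simulate_expression(genes, seed=5):
            if r.direction == "DOWN":
                assert r.log2fc < 0

    def test_p_down_curve_monotone_and_anchored(self):
        eff = syn.NEURON_LENGTH_EFFECT
        lengths = np.logspace(3.0, 6.6, 200)
        p = eff.p_down(lengths)
        assert np.all(np.diff(p) >= -1e-12)
        assert eff.p_down(10_000) == pytest.approx(0.40)
        assert eff.p_down(1_000_000) == pytest.approx(0.80)
        assert eff.p_down(2_500_000) == pytest.approx(0.80)

    def test_empty_genes_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_expression([], syn.NEURON_LENGTH_EFFECT)
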