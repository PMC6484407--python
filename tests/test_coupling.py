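"""Length statistics, RNA maps, dPSI-expression regression, length-bias
curves and gene-set overlap tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polwave import coupling as cp
from polwave import synthetic as syn
from oracles import fisher_enumeration_p


class TestLengthStats:
    def make_group(self, rng, n, scale=1.0):
        return pd.DataFrame({
            "exon_length": rng.lognormal(4.7, 0.5, n),
            "upstream_intron_length": scale * rng.lognormal(7.3, 1.0, n),
            "downstream_intron_length": scale * rng.lognormal(7.3, 1.0, n),
        })

    def test_group_equal_to_background_p_one(self, rng):
        df = self.make_group(rng, 50)
        out = cp.length_stats({"included": df, "all": df.copy()}, background="all")
        assert np.allclose(out["mw_p"], 1.0)

    def test_longer_introns_detected(self, rng):
        groups = {
            "included": self.make_group(rng, 200, scale=1.5),
            "all": self.make_group(rng, 2_000, scale=1.0),
        }
        out = cp.length_stats(groups, background="all").set_index("feature")
        row = out.loc["upstream_intron_length"]
        assert row["mw_p"] < 0.001
        ratio = row["median"] / row["background_median"]
        assert abs(ratio - 1.5) / 1.5 < 0.20

    def test_median_of_three(self):
        df = pd.DataFrame({"exon_length": [1.0, 2.0, 3.0],
                           "upstream_intron_length": [1.0, 2.0, 3.0],
                           "downstream_intron_length": [1.0, 2.0, 3.0]})
        out = cp.length_stats({"g": df, "bg": df.copy()}, background="bg")
        assert (out["median"] == 2.0).all()

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"exon_length": [], "upstream_intron_length": [],
                           "downstream_intron_length": []})
        with pytest.raises(ValueError):
            cp.length_stats({"g": df, "bg": df}, background="bg")


def random_events(rng, n, length=240, plant=None):
    events = []
    for _ in range(n):
        regions = {}
        for region in cp.RNA_MAP_REGIONS:
            extent = 60 if region == "exon" else length
            seq = "".join(rng.choice(list("ACGT"), extent))
            if plant and region == plant[0]:
                pos, motif = plant[1], plant[2]
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            regions[region] = seq
        events.append(regions)
    return events


class TestRnaMap:
    def test_planted_motif_detected(self, rng):
        reg = random_events(rng, 30, plant=("downstream_intron", 20, "TCAT"))
        ctl = random_events(rng, 30)
        result = cp.rna_map({"regulated": reg, "unchanged": ctl}, "YCAY",
                            regulated="regulated", control="unchanged",
                            n_perm=500, seed=1)
        p = result.p_values["downstream_intron"]
        assert p[20:24].max() <= 1.0 / (500 + 1) + 1e-12
        assert result.significant["downstream_intron"][20:24].all()

    def test_null_calibration(self, rng):
        """Random group labels: ~5% of positions significant at 0.05."""
        pool = random_events(rng, 80)
        result = cp.rna_map({"regulated": pool[:40], "unchanged": pool[40:]},
                            "YCAY", regulated="regulated", control="unchanged",
                            n_perm=600, seed=2)
        fracs = [np.mean(result.p_values[r] < 0.05) for r in result.regions]
        assert np.mean(fracs) < 0.12

    def test_p_values_in_half_open_unit_interval(self, rng):
        reg, ctl = random_events(rng, 10), random_events(rng, 10)
        result = cp.rna_map({"regulated": reg, "unchanged": ctl}, "GCATG",
                            regulated="regulated", control="unchanged",
                            n_perm=500, seed=3)
        for region in result.regions:
            assert np.all(result.p_values[region] > 0)
            assert np.all(result.p_values[region] <= 1)
            assert np.all(result.coverage[region]["regulated"] >= 0)
            assert np.all(result.coverage[region]["regulated"] <= 1)

    def test_empty_motif_rejected(self, rng):
        with pytest.raises(ValueError):
            cp.rna_map({"regulated": random_events(rng, 3),
                        "unchanged": random_events(rng, 3)}, "",
                       regulated="regulated", control="unchanged", n_perm=500)

    def test_motif_longer_than_region_rejected(self, rng):
        with pytest.raises(ValueError):
            cp.rna_map({"regulated": random_events(rng, 3),
                        "unchanged": random_events(rng, 3)}, "A" * 100,
                       regulated="regulated", control="unchanged", n_perm=500)

    def test_iupac_degenerate_codes(self):
        pat = cp.iupac_to_regex("YCAY")
        # overlapping matches are found: TCAT at 0, TCAC at 3 share the T
        assert [m.group(1) for m in pat.finditer("TCATCAC")] == ["TCAT", "TCAC"]


class TestDpsiExpressionCorrelation:
    def test_exact_linear_relation_r2_one(self):
        df = pd.DataFrame({"change_class": "both", "log2fc": np.linspace(-2, 2, 50),
                           "dpsi": 10 * np.linspace(-2, 2, 50)})
        out = cp.dpsi_expression_correlation(df)
        assert out.loc[0, "r2"] == pytest.approx(1.0)
        assert out.loc[0, "slope"] == pytest.approx(10.0)

    def test_constant_dpsi_r2_zero(self):
        df = pd.DataFrame({"change_class": "both",
                           "log2fc": np.linspace(-2, 2, 20), "dpsi": 5.0})
        out = cp.dpsi_expression_correlation(df)
        assert out.loc[0, "r2"] == 0.0

    def test_independent_variables_near_zero_r2(self, rng):
        df = pd.DataFrame({"change_class": "changed_AS",
                           "log2fc": rng.normal(size=500),
                           "dpsi": rng.uniform(-30, 30, 500)})
        out = cp.dpsi_expression_correlation(df)
        assert out.loc[0, "r2"] < 0.02

    def test_small_classes_skipped(self):
        df = pd.DataFrame({"change_class": ["tiny", "tiny"], "log2fc": [1.0, 2.0],
                           "dpsi": [5.0, 6.0]})
        assert len(cp.dpsi_expression_correlation(df)) == 0


class TestLengthSlidingWindow:
    def make_records(self, lengths, down_mask):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(lengths))],
            "length": lengths,
            "direction": ["DOWN" if d else "none" for d in down_mask],
        })

    def test_first_window_counts_shortest_genes(self, rng):
        lengths = np.arange(1_000, 301_000, 1_000)  # 300 genes, distinct lengths
        down = np.zeros(300, bool)
        down[rng.choice(100, size=40, replace=False)] = True  # 40 DOWN among shortest 100
        curve = cp.length_sliding_window(self.make_records(lengths, down), window=100)
        assert len(curve) == 201  # N - window + 1
        assert curve.loc[0, "frac_down"] == pytest.approx(0.40)

    def test_no_down_genes_flat_zero(self):
        lengths = np.arange(1_000, 201_000, 1_000)
        curve = cp.length_sliding_window(self.make_records(lengths, np.zeros(200, bool)),
                                         window=100)
        assert (curve["frac_down"] == 0).all()

    def test_neuron_preset_recovery(self):
        """The generator's length effect reappears as a rising curve."""
        genes = syn.make_genes(5_000, length_median=30_000, length_sigma=1.2,
                               min_length=2_000, max_length=2_000_000, seed=6)
        records = syn.simulate_expression(genes, seed=7)
        curve = cp.length_sliding_window(records, window=100)
        smoothed = curve["frac_down"].rolling(500, center=True, min_periods=1).mean()
        rho = stats.spearmanr(curve["median_length"], smoothed).statistic
        assert rho > 0.9

    def test_fraction_invariant_to_order_of_equal_lengths(self):
        lengths = [10_000] * 150
        down = [i < 75 for i in range(150)]
        df1 = self.make_records(lengths, down)
        df2 = df1.iloc[::-1].reset_index(drop=True)
        c1 = cp.length_sliding_window(df1, window=100)
        c2 = cp.length_sliding_window(df2, window=100)
        # every window holds genes of one length; fractions are a set property
        assert sorted(c1["frac_down"]) == sorted(c2["frac_down"])

    def test_fewer_genes_than_window_rejected(self):
        with pytest.raises(ValueError):
            cp.length_sliding_window(self.make_records([1_000] * 50, [False] * 50),
                                     window=100)


class TestOverlapFisher:
    def test_odds_ratio_arithmetic(self):
        universe = {f"g{i}" for i in range(100)}
        ids = sorted(universe)
        query = set(ids[:20])                      # a=10 with annotation
        annotation = set(ids[10:30])
        res = cp.overlap_fisher(query, annotation, universe)
        assert res.table == ((10, 10), (10, 70))
        assert res.odds_ratio == pytest.approx(7.0)  # (10*70)/(10*10)

    def test_degenerate_full_overlap(self):
        universe = {"a", "b", "c"}
        res = cp.overlap_fisher(universe, set(universe), set(universe))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            cp.overlap_fisher(set(), set(), set())

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            cp.overlap_fisher({"x"}, set(), {"a"})

    @pytest.mark.parametrize("table", [(2, 3, 4, 5), (0, 7, 3, 10), (5, 0, 0, 5),
                                       (1, 1, 1, 27), (12, 3, 2, 13)])
    def test_p_matches_hypergeometric_enumeration(self, table):
        a, b, c, d = table
        ids = [f"g{i}" for i in range(a + b + c + d)]
        query = set(ids[: a + b])
        annotation = set(ids[:a]) | set(ids[a + b: a + b + c])
        res = cp.overlap_fisher(query, annotation, set(ids))
        assert res.p_value == pytest.approx(fisher_enumeration_p(a, b, c, d), rel=1e-9)
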