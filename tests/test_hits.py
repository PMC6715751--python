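"""One-sided t-testing, hit flagging, rates, correlations, set overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sirnascreen import (
    HitThresholds,
    SimulationConfig,
    assign_effect_classes,
    call_hits,
    common_hits,
    hit_rate,
    normalize_screen,
    one_sided_t_test,
    percentage,
    simulate_campaign,
    spearman_correlation,
)
from sirnascreen.errors import ConfigError


class TestOneSidedT:
    def test_identical_groups_give_half(self):
        values = [0.0, 0.5, -0.5]
        assert one_sided_t_test(values, values) == pytest.approx(0.5)

    def test_large_separation_gives_tiny_p(self):
        gene = [-10.0, -10.1, -9.9]
        control = [0.0, 0.1, -0.1]
        assert one_sided_t_test(gene, control) < 1e-4

    def test_matches_hand_computed_pooled_t(self):
        # x-bar=-1.1, y-bar=0, s1^2=s2^2=0.01 -> sp^2=0.01,
        # t = -1.1 / (0.1 sqrt(2/3)) = -13.4722, df = 4
        p = one_sided_t_test([-1.2, -1.0, -1.1], [0.0, 0.1, -0.1])
        assert p == pytest.approx(8.781769130823249e-05, rel=1e-9)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(-0.5, 0.3, 5)
            y = rng.normal(0.0, 0.3, 12)
            ours = one_sided_t_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=True, alternative="less").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)
            ours_w = one_sided_t_test(x, y, welch=True)
            ref_w = stats.ttest_ind(x, y, equal_var=False, alternative="less").pvalue
            assert ours_w == pytest.approx(ref_w, rel=1e-9)

    def test_upper_tail_is_complement(self):
        x, y = [-1.0, -1.2, -0.9], [0.0, 0.2, -0.2]
        assert one_sided_t_test(x, y) + one_sided_t_test(x, y, alternative="greater") == pytest.approx(1.0)

    def test_too_few_values_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(one_sided_t_test([1.0], [0.0, 0.1]))


class TestCallHits:
    def _norm_plate(self, gene_values: dict, control=(0.0, 0.1, -0.1, 0.05)):
        rows = []
        for rep, value in enumerate(control, start=1):
            rows.append(("A549", "count2d", "P001", f"C{rep}", "siNC", rep, value))
        for gene, values in gene_values.items():
            for rep, value in enumerate(values, start=1):
                rows.append(("A549", "count2d", "P001", gene, gene, rep, value))
        return pd.DataFrame(
            rows,
            columns=["cell_line", "readout", "plate", "well", "gene_id", "replicate", "log2fc"],
        )

    def test_fold_and_p_criteria_are_both_required(self):
        norm = self._norm_plate(
            {
                "FAILS_FOLD": [-0.9, -0.92, -0.88],   # significant but above -1
                "FAILS_P": [-2.0, 1.0, -5.0],         # deep mean, wild replicates
                "HIT": [-2.0, -2.1, -1.9],
            }
        )
        hits = call_hits(norm).set_index("gene_id")
        assert not hits.loc["FAILS_FOLD", "hit_flag"]
        assert hits.loc["FAILS_FOLD", "p_value"] < 0.01
        assert not hits.loc["FAILS_P", "hit_flag"]
        assert hits.loc["HIT", "hit_flag"]
        # sorted ascending by mean log2fc
        assert list(hits["log2fc_mean"]) == sorted(hits["log2fc_mean"])

    def test_viability_uses_its_own_threshold(self):
        norm = self._norm_plate({"G": [-0.8, -0.82, -0.78]})
        norm["readout"] = "viability2d"
        hits = call_hits(norm).set_index("gene_id")
        assert hits.loc["G", "hit_flag"]  # -0.8 < -0.6 viability cutoff
        strict = call_hits(norm, HitThresholds.twofold_all()).set_index("gene_id")
        assert not strict.loc["G", "hit_flag"]

    def test_threshold_monotonicity(self):
        """Tightening p or fold-change thresholds never adds hits."""
        config = SimulationConfig(n_genes=200, seed=17)
        truth = assign_effect_classes(config)
        norm = normalize_screen(simulate_campaign(config, truth, [("A549", "count2d")]))
        base = call_hits(norm, HitThresholds(p_threshold=0.01))
        tight_p = call_hits(norm, HitThresholds(p_threshold=0.001))
        tight_fc = call_hits(
            norm, HitThresholds(fc_thresholds={"count2d": -1.5, "sphere3d": -1.5, "viability2d": -1.0})
        )
        n_base = base["hit_flag"].sum()
        assert tight_p["hit_flag"].sum() <= n_base
        assert tight_fc["hit_flag"].sum() <= n_base
        hits_of = lambda t: set(t.loc[t["hit_flag"], "gene_id"])
        assert hits_of(tight_p) <= hits_of(base)
        assert hits_of(tight_fc) <= hits_of(base)

    def test_gene_relabeling_permutes_results(self):
        norm = self._norm_plate({"G1": [-2.0, -2.1, -1.9], "G2": [-0.1, 0.0, 0.1]})
        relabeled = norm.replace({"gene_id": {"G1": "Z9", "G2": "A0"}})
        a = call_hits(norm).set_index("gene_id")
        b = call_hits(relabeled).set_index("gene_id").rename(index={"Z9": "G1", "A0": "G2"})
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_recovery_of_planted_effects(self):
        """Planted -2.5 effects at default noise: near-perfect recall, ~0 FPR."""
        config = SimulationConfig(
            n_genes=1000,
            class_proportions={"neutral": 0.95, "two_d_only": 0.05},
            effect_ranges={"two_d_only": {"count2d": (-2.5, -2.5)}},
            seed=11,
        )
        truth = assign_effect_classes(config)
        norm = normalize_screen(simulate_campaign(config, truth, [("A549", "count2d")]))
        hits = call_hits(norm)
        flagged = set(hits.loc[hits["hit_flag"], "gene_id"])
        planted = set(truth.genes_in_class("two_d_only"))
        neutral = set(truth.genes_in_class("neutral"))
        assert len(flagged & planted) / len(planted) >= 0.95
        assert len(flagged & neutral) / len(neutral) <= 0.01


class TestRatesAndCorrelations:
    @pytest.mark.parametrize(
        "n_hits, expected",
        [(195, 4.07), (40, 0.84), (119, 2.49), (141, 2.95), (55, 1.15), (25, 0.52), (0, 0.0)],
    )
    def test_hit_rate_per_screen(self, n_hits, expected):
        assert hit_rate(n_hits, 4786) == expected

    def test_hit_rate_display_precision(self):
        assert hit_rate(302, 4786) == 6.31
        assert hit_rate(302, 4786, decimals=1) == 6.3

    def test_half_up_rounding(self):
        assert percentage(1, 8) == 12.5
        assert percentage(5, 1000, decimals=1) == 0.5
        assert percentage(25, 1000, decimals=0) == 3.0  # 2.5 rounds up, not to even

    def test_hit_rate_input_validation(self):
        with pytest.raises(ValueError):
            hit_rate(5, 0)
        with pytest.raises(ValueError):
            hit_rate(-1, 10)

    def test_spearman_perfect_and_inverted(self):
        a = pd.Series([0.1, -0.5, 0.3, -2.0], index=list("ABCD"))
        assert spearman_correlation(a, a) == pytest.approx(1.0)
        assert spearman_correlation(a, -a) == pytest.approx(-1.0)

    def test_spearman_ties_match_brute_force_ranks(self):
        genes = list("ABCDEFGH")
        a = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0], index=genes)
        b = pd.Series([2.0, 1.0, 4.0, 3.0, 3.0, 6.0, 5.0, 8.0], index=genes)
        # frozen from Pearson correlation of hand-computed average ranks
        assert spearman_correlation(a, b) == pytest.approx(0.8313253012048192, rel=1e-12)

    def test_spearman_needs_three_shared_genes(self):
        a = pd.Series([1.0, 2.0], index=["A", "B"])
        b = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "C"])
        with pytest.warns(UserWarning):
            assert np.isnan(spearman_correlation(a, b))

    def test_common_hits(self, result_table_factory):
        t1 = result_table_factory(
            [("A549", "count2d", g, -2.0, 0.001, True) for g in "ABC"]
            + [("A549", "count2d", "D", -0.1, 0.5, False)]
        )
        t2 = result_table_factory(
            [("HT29", "count2d", g, -2.0, 0.001, True) for g in "BCD"]
        )
        shared, count = common_hits(t1, t2)
        assert shared == {"B", "C"} and count == 2
        assert common_hits(t1, t1)[1] == 3
        disjoint = result_table_factory([("HT29", "count2d", "Z", -2.0, 0.001, True)])
        assert common_hits(t1, disjoint) == (set(), 0)

    def test_planted_overlap_recovered(self):
        """Two lines sharing planted common-essential genes overlap in hits."""
        config = SimulationConfig(
            n_genes=300,
            class_proportions={"neutral": 0.9, "common_essential": 0.1},
            seed=29,
        )
        truth = assign_effect_classes(config)
        raw = simulate_campaign(config, truth, [("A549", "count2d"), ("HT29", "count2d")])
        hits = call_hits(normalize_screen(raw))
        a = hits[hits["cell_line"] == "A549"]
        b = hits[hits["cell_line"] == "HT29"]
        planted = set(truth.genes_in_class("common_essential"))
        shared, count = common_hits(a, b)
        assert planted <= shared
        assert count - len(planted) <= np.ceil(0.01 * config.n_genes) + 3


def test_bad_thresholds_rejected():
    with pytest.raises(ConfigError):
        HitThresholds(p_threshold=1.5)
    with pytest.raises(ConfigError):
        HitThresholds(fc_thresholds={"count2d": 1.0})
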