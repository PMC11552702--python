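"""Between-sample comparisons: summaries, bootstrap inference, state-space differences."""

import numpy as np
import pytest

import matplotlib

matplotlib.use("Agg")

from mobqol import (
    anchoring_summary,
    build_puf,
    coefficient_differences,
    dimension_weighting,
    extreme_state_table,
    level_rating_summary,
    tabulate_all_states,
    utility_difference_distribution,
)
from mobqol.compare import plot_sorted_utilities, plot_utility_histogram
from mobqol.states import DIMENSIONS

from .conftest import make_record, random_record


class TestLevelRatingSummary:
    def test_identical_records(self):
        recs = [make_record(rid=f"r{i}", vas_l2={c: 60.0 for c in DIMENSIONS}) for i in range(5)]
        out = level_rating_summary(recs)
        assert np.all(out["level2_mean"] == 60.0)
        assert np.all(out["level2_sd"] == 0.0)
        assert np.all(out["level1"] == 100.0) and np.all(out["level4"] == 0.0)

    def test_two_record_hand_arithmetic(self):
        recs = [
            make_record(rid="a", vas_l2={c: 40.0 for c in DIMENSIONS}),
            make_record(rid="b", vas_l2={c: 80.0 for c in DIMENSIONS}),
        ]
        out = level_rating_summary(recs)
        assert np.all(out["level2_mean"] == 60.0)
        assert out["level2_sd"].iloc[0] == pytest.approx(28.2843, abs=1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            level_rating_summary([])


class TestDimensionWeighting:
    def test_dominant_dimension_ranks_first(self):
        weights = {c: 50.0 for c in DIMENSIONS}
        weights["PD"] = 100.0
        recs = [make_record(rid=f"r{i}", weights=dict(weights), yardstick="PD") for i in range(4)]
        out = dimension_weighting(recs).set_index("dimension")
        assert out.loc["PD", "rank"] == 1

    def test_exact_ties_broken_by_canonical_order(self):
        recs = [make_record(rid="r0")]  # all weights equal
        out = dimension_weighting(recs)
        assert list(out["rank"]) == [1, 2, 3, 4, 5, 6, 7]  # AC, CO, PD, IN, SE, ME, AX


class TestCoefficientDifferences:
    def test_self_comparison_is_identically_zero(self):
        rng = np.random.default_rng(21)
        pufs = [build_puf(random_record(rng, rid=f"r{i}")) for i in range(20)]
        out = coefficient_differences(pufs, pufs, iterations=300, seed=4)
        assert out["difference"].to_numpy() == pytest.approx(np.zeros(21), abs=1e-12)
        assert not out["significant"].any()

    def test_singletons_give_decrement_gap_with_degenerate_ci(self):
        a = build_puf(make_record(rid="a", anchor_vas=40.0))
        b = build_puf(make_record(rid="b", anchor_vas=20.0))
        out = coefficient_differences([a], [b], iterations=50, seed=0)
        gap = a.decrements - b.decrements
        for _, row in out.iterrows():
            d = DIMENSIONS.index(row["dimension"])
            assert row["difference"] == pytest.approx(gap[d, row["level"] - 1], abs=1e-12)
            assert row["ci_low"] == pytest.approx(row["difference"], abs=1e-12)
            assert row["ci_high"] == pytest.approx(row["difference"], abs=1e-12)

    def test_planted_effect_recovered_and_flagged(self):
        """Samples differing only in the PD level-2 rating show the planted gap."""
        rng = np.random.default_rng(22)
        n = 120

        def sample(center):
            recs = []
            for i in range(n):
                vas_l2 = {c: 70.0 for c in DIMENSIONS}
                vas_l2["PD"] = float(rng.uniform(center - 15, center + 15))
                recs.append(make_record(rid=f"r{i}", vas_l2=vas_l2))
            return [build_puf(r) for r in recs]

        pufs_a, pufs_b = sample(70.0), sample(50.0)
        out = coefficient_differences(pufs_a, pufs_b, iterations=1000, seed=5)
        row = out[(out["dimension"] == "PD") & (out["level"] == 2)].iloc[0]
        # planted gap: (1/7) * (0.5 - 0.3) * (1 - 0.3) = -0.02 (A less severe)
        planted = (1 / 7) * (0.3 - 0.5) * 0.7
        se = 2 * ((15 / np.sqrt(3)) / 100 / 7 * 0.7) / np.sqrt(n)  # 2-sample SE
        assert abs(row["difference"] - planted) < 2 * se
        assert row["significant"]
        other = out[(out["dimension"] != "PD") | (out["level"] != 2)]
        assert not other["significant"].any()


class TestAnchoringSummary:
    def test_unanimous_worst_preferred(self):
        recs = [make_record(rid=f"r{i}", anchor_vas=100.0) for i in range(4)]
        out = anchoring_summary(recs)
        assert out["pct_worst_preferred"] == 100.0
        assert out["mean_anchor"] == pytest.approx(1.0)
        assert out["n_below_minus1"] == 0

    def test_capped_anchor_counted_below_minus_one(self):
        recs = [
            make_record(rid="a", anchor_vas=50.0),
            make_record(rid="b", branch="dead_preferred", anchor_vas=80.0),
        ]
        out = anchoring_summary(recs)
        assert out["n_below_minus1"] == 1
        assert out["pct_worst_preferred"] == 50.0
        assert out["mean_anchor"] == pytest.approx((0.5 + -1.0) / 2)


class TestUtilityDifferenceDistribution:
    def test_self_difference_is_zero(self, gp_vs):
        out = utility_difference_distribution(gp_vs, gp_vs)
        assert out["mean"] == 0.0 and out["sd"] == 0.0

    def test_published_sets_mean_and_sd(self, gp_vs, mi_vs):
        out = utility_difference_distribution(gp_vs, mi_vs)
        assert out["mean"] == pytest.approx(-0.039, abs=5e-4)
        assert out["sd"] == pytest.approx(0.016, abs=5e-4)

    def test_mean_agrees_with_closed_form_oracle(self, gp_vs, mi_vs):
        """Uniform enumeration: E[diff] = -sum_d mean-over-levels decrement gap."""
        closed = -(gp_vs.decrements - mi_vs.decrements).mean(axis=1).sum()
        out = utility_difference_distribution(gp_vs, mi_vs)
        assert out["mean"] == pytest.approx(closed, abs=1e-12)


class TestExtremeStateTable:
    def test_k1_gives_best_and_worst_only(self, gp_vs, mi_vs):
        out = extreme_state_table(gp_vs, mi_vs, k=1)
        assert list(out["state"]) == ["1111111", "4444444"]

    def test_bottom25_mean_difference_matches_published(self, gp_vs, mi_vs):
        out = extreme_state_table(gp_vs, mi_vs, k=25)
        bottom = out.tail(25)
        assert bottom["difference"].mean() == pytest.approx(-0.073, abs=0.002)
        worst = out.iloc[-1]
        assert worst["state"] == "4444444"
        assert worst["difference"] == pytest.approx(-0.072, abs=1e-9)

    def test_rows_consistent_with_full_tabulation(self, gp_vs, mi_vs):
        out = extreme_state_table(gp_vs, mi_vs, k=5)
        ta = tabulate_all_states(gp_vs).set_index("state")
        tb = tabulate_all_states(mi_vs).set_index("state")
        for _, row in out.iterrows():
            assert row["rank_a"] == ta.loc[row["state"], "rank"]
            assert row["rank_b"] == tb.loc[row["state"], "rank"]
            assert row["rank_difference"] == row["rank_b"] - row["rank_a"]


def test_plotting_smoke(gp_vs, mi_vs):
    ax1 = plot_utility_histogram(gp_vs, mi_vs)
    assert len(ax1.patches) > 0
    ax2 = plot_sorted_utilities(gp_vs, mi_vs)
    assert len(ax2.lines) == 2
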