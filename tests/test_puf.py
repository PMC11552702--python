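"""Personal utility function construction: rescaling, weights, anchoring, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobqol import (
    AnchoringResponse,
    HealthState,
    SwingWeights,
    ValidationError,
    build_puf,
    compute_anchor,
    normalize_weights,
    parse_state_index,
    puf_utility,
    raw_anchor,
    rescale_level_ratings,
    validate_respondent,
)
from mobqol.puf import apply_qc_policy
from mobqol.states import DIMENSIONS

from .conftest import make_record, random_record


class TestLevelRescaling:
    def test_anchors_and_midpoints(self):
        rec = make_record(
            vas_l2={c: 100.0 for c in DIMENSIONS}, vas_l3={c: 0.0 for c in DIMENSIONS}
        )
        sev = rescale_level_ratings(rec.level_ratings)
        assert np.all(sev[:, 0] == 0.0)  # level 1 is the best anchor
        assert np.all(sev[:, 1] == 0.0)  # VAS 100 coincides with best
        assert np.all(sev[:, 2] == 1.0)  # VAS 0 coincides with worst
        assert np.all(sev[:, 3] == 1.0)  # level 4 is the worst anchor

    def test_published_mean_example(self):
        # a VAS position of 72.9 (the GP-sample Independence level-2 mean)
        rec = make_record(vas_l2={c: 72.9 for c in DIMENSIONS})
        sev = rescale_level_ratings(rec.level_ratings)
        assert sev[:, 1] == pytest.approx(0.271)

    def test_out_of_range_raises(self):
        rec = make_record(vas_l2={**{c: 50.0 for c in DIMENSIONS}, "PD": 101.0})
        with pytest.raises(ValidationError, match=r"vas_level2\[PD\]"):
            rescale_level_ratings(rec.level_ratings)


class TestWeightNormalisation:
    def test_symmetry(self):
        w = normalize_weights(SwingWeights(raw={c: 100.0 for c in DIMENSIONS}, most_impactful="AC"))
        assert w == pytest.approx(np.full(7, 1 / 7))

    def test_degenerate_single_dimension(self):
        raw = {c: 0.0 for c in DIMENSIONS}
        raw["AC"] = 100.0
        w = normalize_weights(SwingWeights(raw=raw, most_impactful="AC"))
        assert w == pytest.approx([1, 0, 0, 0, 0, 0, 0])

    def test_proportionality(self):
        raw = {c: 0.0 for c in DIMENSIONS}
        raw.update({"AC": 100.0, "CO": 50.0, "PD": 50.0})
        w = normalize_weights(SwingWeights(raw=raw, most_impactful="AC"))
        assert w == pytest.approx([0.5, 0.25, 0.25, 0, 0, 0, 0])

    def test_yardstick_must_be_pinned_at_100(self):
        with pytest.raises(ValidationError, match="yardstick"):
            SwingWeights(raw={c: 50.0 for c in DIMENSIONS}, most_impactful="AC")


class TestAnchoring:
    @pytest.mark.parametrize(
        "branch,pos,expected",
        [
            ("worst_preferred", 50.0, 0.5),
            ("worst_preferred", 0.0, 0.0),
            ("worst_preferred", 100.0, 1.0),
            ("dead_preferred", 0.0, 0.0),
            ("dead_preferred", 20.0, -0.25),
            ("dead_preferred", 50.0, -1.0),
            ("dead_preferred", 80.0, -1.0),  # raw -4, capped
            ("dead_preferred", 100.0, -1.0),  # limiting case of the projective map
        ],
    )
    def test_anchor_values(self, branch, pos, expected):
        assert compute_anchor(AnchoringResponse(branch=branch, vas_position=pos)) == pytest.approx(
            expected
        )

    def test_branch_continuity_at_indifference(self):
        a = compute_anchor(AnchoringResponse(branch="worst_preferred", vas_position=0.0))
        b = compute_anchor(AnchoringResponse(branch="dead_preferred", vas_position=0.0))
        assert a == b == 0.0

    @pytest.mark.parametrize("q", [0.0, 10.0, 49.0, 49.999, 50.0, 50.001, 75.0, 99.0])
    def test_cap_engages_iff_position_exceeds_midpoint(self, q):
        resp = AnchoringResponse(branch="dead_preferred", vas_position=q)
        capped = compute_anchor(resp) == -1.0 and raw_anchor(resp) < -1.0
        assert capped == (q > 50.0)

    def test_out_of_range_position_raises(self):
        with pytest.raises(ValidationError):
            compute_anchor(AnchoringResponse(branch="worst_preferred", vas_position=120.0))


class TestBuildPuf:
    def test_uniform_symmetric_construction(self, uniform_record):
        puf = build_puf(uniform_record)
        assert puf.anchor == pytest.approx(0.3)
        assert puf.decrements[:, 3] == pytest.approx(np.full(7, 0.1))
        assert puf_utility(puf, parse_state_index("1111111")) == pytest.approx(1.0)
        assert puf_utility(puf, parse_state_index("4111111")) == pytest.approx(0.9)
        assert puf_utility(puf, parse_state_index("4444444")) == pytest.approx(0.3)

    def test_flat_preference_when_worst_equals_full_health(self):
        rec = make_record(anchor_vas=100.0)
        puf = build_puf(rec)
        assert np.all(puf.decrements == 0.0)
        assert puf_utility(puf, parse_state_index("3232123")) == 1.0

    def test_invariants_on_random_records(self):
        rng = np.random.default_rng(7)
        for i in range(50):
            puf = build_puf(random_record(rng, rid=f"r{i}"))
            assert puf.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert -1.0 <= puf.anchor <= 1.0
            assert puf.decrements[:, 0] == pytest.approx(np.zeros(7))
            assert puf.decrements[:, 3].sum() == pytest.approx(1.0 - puf.anchor, abs=1e-9)

    def test_matrix_evaluation_agrees_with_bruteforce_over_full_space(self):
        """Oracle equivalence: decrement lookup vs direct 1 - sum(w*s*(1-u))."""
        rng = np.random.default_rng(11)
        rec = random_record(rng)
        puf = build_puf(rec)
        w, sev, anchor = puf.weights, puf.severities, puf.anchor
        from mobqol import enumerate_states

        for state in enumerate_states():
            direct = 1.0 - sum(
                w[d] * sev[d, state.levels[d] - 1] * (1.0 - anchor) for d in range(7)
            )
            assert abs(puf_utility(puf, state) - direct) < 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        levels=st.lists(st.integers(1, 4), min_size=7, max_size=7),
        bumps=st.lists(st.integers(0, 3), min_size=7, max_size=7),
    )
    def test_monotonicity_under_dominance_for_monotone_ratings(self, levels, bumps):
        rec = make_record(
            vas_l2={c: 70.0 for c in DIMENSIONS}, vas_l3={c: 30.0 for c in DIMENSIONS}
        )
        puf = build_puf(rec)
        better = HealthState(tuple(levels))
        worse = HealthState(tuple(min(l + b, 4) for l, b in zip(levels, bumps)))
        assert puf_utility(puf, better) >= puf_utility(puf, worse) - 1e-12


class TestQualityControl:
    def test_clean_record_has_no_flags(self, uniform_record):
        assert validate_respondent(uniform_record) == []

    def test_nonmonotone_levels_flagged(self):
        rec = make_record(
            vas_l2={**{c: 70.0 for c in DIMENSIONS}, "SE": 20.0},
            vas_l3={**{c: 30.0 for c in DIMENSIONS}, "SE": 80.0},
        )
        assert validate_respondent(rec) == ["NONMONOTONE_LEVELS"]

    def test_all_zero_weights_flagged(self):
        rec = make_record(weights={**{c: 0.0 for c in DIMENSIONS}, "AC": 100.0})
        # zero out the yardstick after construction to emulate corrupt input
        object.__setattr__(rec.swing_weights, "raw", {c: 0.0 for c in DIMENSIONS})
        assert "ALL_ZERO_WEIGHTS" in validate_respondent(rec)

    def test_range_violation_and_inversion_flagged(self):
        rec = make_record()
        object.__setattr__(rec.anchoring, "vas_position", 130.0)
        flags = validate_respondent(rec)
        assert "RANGE_VIOLATION" in flags
        assert "INVERTED_GLOBAL" in flags

    def test_qc_policy_excludes_structural_failures_only(self):
        clean = make_record(rid="ok")
        nonmono = make_record(
            rid="nm",
            vas_l2={**{c: 70.0 for c in DIMENSIONS}, "SE": 20.0},
            vas_l3={**{c: 30.0 for c in DIMENSIONS}, "SE": 80.0},
        )
        inverted = make_record(rid="inv")
        object.__setattr__(inverted.anchoring, "vas_position", 130.0)

        kept, flags = apply_qc_policy([clean, nonmono, inverted], policy="default")
        assert [r.id for r in kept] == ["ok", "nm"]
        assert set(flags) == {"nm", "inv"}

        kept_all, _ = apply_qc_policy([clean, nonmono, inverted], policy="keep-all")
        assert len(kept_all) == 3

        kept_strict, _ = apply_qc_policy([clean, nonmono, inverted], policy="strict")
        assert [r.id for r in kept_strict] == ["ok"]
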