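import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stepmeta as sm
from stepmeta.patterns import (
    DirectionTrend,
    Pattern,
    Verdict,
    classify_trajectory,
    interpret,
)


def traj(*pairs):
    """Build a ratio-measure trajectory from (display_effect, se) pairs."""
    import math

    return [
        sm.estimate_from_theta(math.log(eff), se, 0.95, "ratio") for eff, se in pairs
    ]


class TestWorkedExamples:
    def test_ascending_gaining_significance(self, gastric_strata):
        _, ests = gastric_strata
        cls = classify_trajectory(ests)
        assert cls.pattern is Pattern.P1_ASCENDING_GAINING_SIGNIFICANCE
        assert cls.direction_trend is DirectionTrend.ASCENDING
        assert cls.verdict is Verdict.SUPPORTED_STRENGTHENED
        assert cls.significant_flags == (False, True, True)
        assert cls.top_significant
        # the .053 stage is flagged marginally nonsignificant
        assert cls.marginal_flags == (True, False, False)

    def test_descending_all_significant(self, oligometastases_strata):
        _, ests = oligometastases_strata
        cls = classify_trajectory(ests)
        assert cls.pattern is Pattern.P4_DESCENDING_ALL_SIGNIFICANT
        assert cls.direction_trend is DirectionTrend.DESCENDING
        assert cls.verdict is Verdict.SUPPORTED_WEAKENED
        assert cls.significant_flags == (True, True, True)


class TestArchetypes:
    def test_contradictory_opposite_significant_directions(self):
        cls = classify_trajectory(traj((1.20, 0.05), (0.83, 0.05)))
        assert cls.pattern is Pattern.CONTRADICTORY
        # verdict weighted to the (significant) randomized stratum
        assert cls.verdict is Verdict.SUPPORTED

    def test_concordant_identical_significant_effects(self):
        cls = classify_trajectory(traj((1.40, 0.12), (1.40, 0.12), (1.40, 0.12)))
        assert cls.pattern is Pattern.CONCORDANT
        assert cls.direction_trend is DirectionTrend.FLAT
        assert cls.verdict is Verdict.SUPPORTED

    def test_ascending_all_significant(self):
        cls = classify_trajectory(traj((1.30, 0.08), (1.45, 0.08), (1.60, 0.08)))
        assert cls.pattern is Pattern.P2_ASCENDING_ALL_SIGNIFICANT
        assert cls.verdict is Verdict.SUPPORTED_STRENGTHENED

    def test_descending_losing_significance(self):
        cls = classify_trajectory(traj((1.60, 0.08), (1.30, 0.08), (1.05, 0.20)))
        assert cls.pattern is Pattern.P3_DESCENDING_LOSING_SIGNIFICANCE
        assert not cls.top_significant
        assert cls.verdict is Verdict.REJECTED

    def test_non_monotone_is_indeterminate(self):
        cls = classify_trajectory(traj((1.30, 0.08), (1.80, 0.08), (1.35, 0.08)))
        assert cls.pattern is Pattern.INDETERMINATE
        assert cls.direction_trend is DirectionTrend.NON_MONOTONE

    def test_flat_dead_band(self):
        # ~0.15% relative steps in |log effect| sit inside the 1% dead-band
        cls = classify_trajectory(traj((1.400, 0.05), (1.4007, 0.05), (1.4014, 0.05)))
        assert cls.direction_trend is DirectionTrend.FLAT
        assert cls.pattern is Pattern.CONCORDANT


class TestErrorsAndOrdering:
    def test_fewer_than_two_strata_raises(self):
        with pytest.raises(ValueError):
            classify_trajectory(traj((1.4, 0.1)))

    def test_unordered_stratum_results_raise(self):
        ests = traj((1.2, 0.1), (1.4, 0.1))
        s1 = sm.pool_random_dl([ests[0]], label="a", level_index=2)
        s2 = sm.pool_random_dl([ests[1]], label="b", level_index=1)
        with pytest.raises(ValueError, match="strictly increasing"):
            classify_trajectory([s1, s2])

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError):
            classify_trajectory(traj((1.2, 0.1), (1.4, 0.1)), alpha=0.0)


@st.composite
def trajectories(draw):
    k = draw(st.integers(2, 5))
    thetas = draw(st.lists(st.floats(-1.5, 1.5), min_size=k, max_size=k))
    ses = draw(st.lists(st.floats(0.02, 0.8), min_size=k, max_size=k))
    return [sm.estimate_from_theta(t, s, 0.95, "ratio") for t, s in zip(thetas, ses)]


class TestClassifierProperties:
    @given(ests=trajectories())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_total_single_valued_and_internally_consistent(self, ests):
        """Every valid trajectory yields exactly one pattern whose own
        invariants (trend/significance implications) hold."""
        cls = classify_trajectory(ests)
        assert isinstance(cls.pattern, Pattern)
        assert isinstance(cls.verdict, Verdict)
        if cls.pattern in (
            Pattern.P1_ASCENDING_GAINING_SIGNIFICANCE,
            Pattern.P2_ASCENDING_ALL_SIGNIFICANT,
        ):
            assert cls.direction_trend is DirectionTrend.ASCENDING
            assert cls.top_significant
        if cls.pattern is Pattern.P3_DESCENDING_LOSING_SIGNIFICANCE:
            assert not cls.top_significant
            assert cls.verdict is Verdict.REJECTED
        if cls.pattern is Pattern.P4_DESCENDING_ALL_SIGNIFICANT:
            assert all(cls.significant_flags)
            assert cls.verdict is Verdict.SUPPORTED_WEAKENED

    @given(ests=trajectories())
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_reciprocal_scale_invariance(self, ests):
        """Inverting every ratio effect (and swapping CI bounds) must not
        change the classification."""
        inverted = [
            sm.make_estimate(
                1 / e.display_value, 1 / e.ci_upper, 1 / e.ci_lower, e.ci_level, "ratio"
            )
            for e in ests
        ]
        a = classify_trajectory(ests)
        b = classify_trajectory(inverted)
        assert a.pattern is b.pattern
        assert a.direction_trend is b.direction_trend
        assert a.verdict is b.verdict

    @given(ests=trajectories(), a1=st.floats(0.01, 0.2), a2=st.floats(0.01, 0.2))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_alpha_monotonicity(self, ests, a1, a2):
        """Raising alpha can only turn flags significant, never the reverse."""
        lo, hi = sorted((a1, a2))
        flags_lo = classify_trajectory(ests, alpha=lo).significant_flags
        flags_hi = classify_trajectory(ests, alpha=hi).significant_flags
        assert all(not f_lo or f_hi for f_lo, f_hi in zip(flags_lo, flags_hi))


class TestInterpret:
    def test_ascending_reports_underestimation(self, gastric_strata):
        _, ests = gastric_strata
        report = interpret(classify_trajectory(ests))
        assert "lower than the true effect" in report["interpretation"]
        assert report["verdict"] == "supported_strengthened"

    def test_descending_reports_overestimation(self, oligometastases_strata):
        _, ests = oligometastases_strata
        report = interpret(classify_trajectory(ests))
        assert "larger than the true effect" in report["interpretation"]

    def test_concordant_states_hypothesis_true_without_trend(self):
        report = interpret(
            classify_trajectory(traj((1.4, 0.12), (1.4, 0.12), (1.4, 0.12)))
        )
        assert "hypothesis is true" in report["interpretation"]
        assert "Confounding diagnosis" not in report["interpretation"]

    def test_report_is_json_serialisable(self, gastric_strata):
        import json

        _, ests = gastric_strata
        json.dumps(interpret(classify_trajectory(ests)))
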