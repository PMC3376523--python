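"""Break-even solver: exact integer scan, legacy rounded ratio, sweeps."""
from dataclasses import replace
from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from eduecon.breakeven import (
    BreakEvenScenario,
    FacilitatorTerms,
    ProfitabilitySegments,
    breakeven_curve,
    breakeven_rounded_ratio,
    breakeven_segments,
    net_position,
    sensitivity_sweep,
)


def naive_profitable_set(fc, vc, fee, capacity, max_enrollments):
    """Independent oracle: exact rational arithmetic, class-by-class fill."""
    profitable = set()
    for q in range(1, max_enrollments + 1):
        classes, remaining = 0, q
        while remaining > 0:
            classes += 1
            remaining -= capacity
        cost = Fraction(fc) * classes + Fraction(vc) * q
        if Fraction(fee) * q >= cost:
            profitable.add(q)
    return profitable


def segments_as_set(segments: ProfitabilitySegments) -> set:
    return {q for a, b in segments.segments for q in range(a, b + 1)}


scenario_strategy = st.builds(
    BreakEvenScenario,
    fixed_per_class=st.integers(min_value=0, max_value=6000).map(Decimal),
    variable_per_participant=st.integers(min_value=0, max_value=300).map(Decimal),
    enrollment_fee=st.integers(min_value=0, max_value=1200).map(Decimal),
    class_capacity=st.integers(min_value=1, max_value=30),
    max_enrollments=st.integers(min_value=1, max_value=80),
)


class TestNetPosition:
    def test_web_primary_values(self, web_primary):
        assert net_position(7, web_primary) == Decimal("104.00")
        assert net_position(6, web_primary) == Decimal("-138.00")
        assert net_position(0, web_primary) == Decimal("0.00")

    def test_out_of_range_rejected(self, web_primary):
        with pytest.raises(ValueError):
            net_position(61, web_primary)
        with pytest.raises(ValueError):
            net_position(-1, web_primary)


class TestBreakevenSegments:
    def test_web_primary_single_segment(self, web_primary):
        segs = breakeven_segments(web_primary)
        assert segs.segments == ((7, 60),)
        assert segs.first_break_even == 7
        assert segs.breaks_even

    def test_f2f_primary_three_segments(self, f2f_primary):
        segs = breakeven_segments(f2f_primary)
        assert segs.segments == ((15, 20), (29, 40), (43, 60))

    def test_never_breaks_even_when_fee_below_variable_cost(self, web_primary):
        sc = replace(web_primary, enrollment_fee=Decimal("5"))
        segs = breakeven_segments(sc)
        assert segs.segments == ()
        assert not segs.breaks_even
        assert segs.first_break_even is None

    def test_exact_zero_net_counts_as_break_even(self, f2f_primary):
        # 3060 / (800 - 35) = 4 exactly
        sc = replace(f2f_primary, enrollment_fee=Decimal("800"))
        assert net_position(4, sc) == Decimal("0.00")
        assert breakeven_segments(sc).first_break_even == 4

    def test_no_fixed_costs_and_ample_capacity_profitable_everywhere(self):
        sc = BreakEvenScenario(Decimal("0"), Decimal("8"), Decimal("250"), 60, 60)
        assert breakeven_segments(sc).segments == ((1, 60),)

    def test_segment_rendering_dialect(self, f2f_primary):
        assert str(breakeven_segments(f2f_primary)) == "15–20; 29–40; 43–60"
        sc = replace(f2f_primary, enrollment_fee=Decimal("5"))
        assert str(breakeven_segments(sc)) == "does not break even"

    @given(scenario=scenario_strategy)
    @settings(max_examples=150, derandomize=True)
    def test_matches_naive_oracle(self, scenario):
        expected = naive_profitable_set(
            int(scenario.fixed_per_class),
            int(scenario.variable_per_participant),
            int(scenario.enrollment_fee),
            scenario.class_capacity,
            scenario.max_enrollments,
        )
        assert segments_as_set(breakeven_segments(scenario)) == expected

    @given(scenario=scenario_strategy, bump=st.integers(min_value=1, max_value=400))
    @settings(max_examples=100, derandomize=True)
    def test_raising_fee_never_shrinks_segments(self, scenario, bump):
        before = segments_as_set(breakeven_segments(scenario))
        richer = replace(
            scenario, enrollment_fee=scenario.enrollment_fee + Decimal(bump)
        )
        assert before <= segments_as_set(breakeven_segments(richer))

    @given(scenario=scenario_strategy, bump=st.integers(min_value=1, max_value=2000))
    @settings(max_examples=100, derandomize=True)
    def test_raising_costs_never_grows_segments(self, scenario, bump):
        before = segments_as_set(breakeven_segments(scenario))
        dearer_fixed = replace(
            scenario, fixed_per_class=scenario.fixed_per_class + Decimal(bump)
        )
        assert segments_as_set(breakeven_segments(dearer_fixed)) <= before
        dearer_variable = replace(
            scenario,
            variable_per_participant=scenario.variable_per_participant + Decimal(bump),
        )
        assert segments_as_set(breakeven_segments(dearer_variable)) <= before


class TestRoundedRatio:
    def test_published_headline_numbers(self, web_primary, f2f_primary):
        assert breakeven_rounded_ratio(web_primary) == 7
        assert breakeven_rounded_ratio(f2f_primary) == 14  # 3060/215 = 14.23

    def test_all_costs_halved(self, web_primary):
        halved = BreakEvenScenario(Decimal("795"), Decimal("4"), Decimal("250"), 20)
        assert breakeven_rounded_ratio(halved) == 3

    def test_none_when_margin_nonpositive(self, web_primary):
        assert breakeven_rounded_ratio(
            replace(web_primary, enrollment_fee=Decimal("8"))
        ) is None

    def test_half_up_rounding(self):
        # 100/8 = 12.5 rounds up, not banker's to 12
        sc = BreakEvenScenario(Decimal("100"), Decimal("0"), Decimal("8"), 20)
        assert breakeven_rounded_ratio(sc) == 13


class TestSensitivitySweep:
    def test_capacity_sweep_always_breaks_even_at_seven(self, web_primary):
        rows = sensitivity_sweep(
            web_primary, "class_capacity", [10, 30, 40, 50, 60]
        )
        assert [r.segments.first_break_even for r in rows] == [7] * 5

    def test_doubling_all_costs_sinks_face_to_face(self, f2f_primary):
        (row,) = sensitivity_sweep(f2f_primary, "all_costs_scale", [2.0])
        assert not row.segments.breaks_even
        assert row.scenario.fixed_per_class == Decimal("6120.00")
        assert row.scenario.variable_per_participant == Decimal("70.00")

    def test_low_fee_multi_segment_scan(self, web_primary):
        (row,) = sensitivity_sweep(web_primary, "enrollment_fee", [100])
        assert row.segments.segments == ((18, 20), (35, 40), (52, 60))

    def test_facilitator_axes_rebuild_fixed_cost(self, web_primary):
        terms = FacilitatorTerms(hours=14, rate=Decimal("60"), other_fixed=Decimal("750"))
        (row,) = sensitivity_sweep(web_primary, "facilitator_hours", [48], terms)
        assert row.scenario.fixed_per_class == Decimal("3630.00")  # 48*60 + 750
        assert row.segments.segments == ((15, 20), (30, 40), (45, 60))
        (row,) = sensitivity_sweep(web_primary, "facilitator_rate", [200], terms)
        assert row.scenario.fixed_per_class == Decimal("3550.00")  # 14*200 + 750
        assert row.segments.segments == ((15, 20), (30, 40), (45, 60))

    def test_facilitator_axis_requires_terms(self, web_primary):
        with pytest.raises(ValueError):
            sensitivity_sweep(web_primary, "facilitator_hours", [8])

    def test_unknown_axis_rejected(self, web_primary):
        with pytest.raises(ValueError):
            sensitivity_sweep(web_primary, "weather", [1])


class TestBreakevenCurve:
    def test_curve_net_matches_net_position(self, f2f_primary):
        curve = breakeven_curve(f2f_primary)
        assert len(curve) == 61
        for q in (0, 7, 20, 21, 43):
            row = curve.iloc[q]
            assert row["net"] == pytest.approx(float(net_position(q, f2f_primary)))
            assert row["savings"] - row["cost"] == pytest.approx(row["net"])
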