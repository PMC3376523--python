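"""Participant expenses, WTP aggregation, net benefit, construct validity."""
import math
from decimal import Decimal

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eduecon.cba import (
    CBAScenario,
    WTPResponse,
    cba_sensitivity_table,
    mean_wtp,
    net_benefit,
    participant_expense,
    spearman_validity,
    wtp_construct_validity,
)
from eduecon.cost_model import FACE_TO_FACE, WEB


class TestParticipantExpense:
    def test_primary_totals(self):
        f2f = participant_expense(FACE_TO_FACE, 250, 12)
        assert f2f.total == Decimal("810.00")
        assert f2f.transport == Decimal("20.00")
        assert f2f.downloads == Decimal("0.00")
        web = participant_expense(WEB, 250, 14.4)
        assert web.total == Decimal("918.00")
        assert web.downloads == Decimal("20.00")
        assert web.transport == Decimal("0.00")

    def test_satellite_variant(self):
        web = participant_expense(WEB, 250, 14.4, internet_variant="satellite")
        assert web.total == Decimal("923.00")

    def test_leisure_applies_penalty_loading(self):
        f2f = participant_expense(FACE_TO_FACE, 250, 12, timing="leisure")
        assert f2f.time_cost == Decimal("810.00")  # 12 x 45 x 1.5
        assert f2f.total == Decimal("1080.00")

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            participant_expense(WEB, 250, 14.4, internet_variant="carrier-pigeon")

    @given(k=st.integers(min_value=1, max_value=8))
    @settings(max_examples=20, derandomize=True)
    def test_total_homogeneous_under_component_scaling(self, k):
        base = participant_expense(WEB, 250, 14.4)
        scaled = base.scaled(k)
        assert scaled.total == k * base.total
        assert scaled.downloads == k * base.downloads


class TestMeanWTP:
    @staticmethod
    def responses(amounts, arm=WEB, context=1):
        return [
            WTPResponse(f"p{i}", arm, context, amount=a)
            for i, a in enumerate(amounts)
        ]

    def test_hand_computed_mean_and_sd(self):
        summary = mean_wtp(self.responses([100, 200, 180]), WEB, 1)
        assert summary == type(summary)(3, Decimal("160.00"), Decimal("52.92"))

    def test_single_response_has_no_sd(self):
        summary = mean_wtp(self.responses([123]), WEB, 1)
        assert (summary.n, summary.mean, summary.sd) == (1, Decimal("123.00"), None)

    def test_all_missing_yields_empty_marker(self):
        rs = [WTPResponse("p0", WEB, 1, amount=None)]
        summary = mean_wtp(rs, WEB, 1)
        assert summary.empty and summary.mean is None

    def test_filters_by_arm_and_context(self):
        rs = self.responses([100], WEB, 1) + self.responses([900], FACE_TO_FACE, 1)
        assert mean_wtp(rs, WEB, 1).mean == Decimal("100.00")
        assert mean_wtp(rs, WEB, 2).empty

    @given(
        amounts=st.lists(
            st.integers(min_value=0, max_value=1000), min_size=2, max_size=20
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_two_pass_oracle(self, amounts):
        summary = mean_wtp(self.responses(amounts), WEB, 1)
        mean = sum(amounts) / len(amounts)
        sd = math.sqrt(sum((a - mean) ** 2 for a in amounts) / (len(amounts) - 1))
        assert float(summary.mean) == pytest.approx(mean, abs=0.005)
        assert float(summary.sd) == pytest.approx(sd, abs=0.005)


class TestNetBenefit:
    def test_identical_arms_cancel(self):
        assert net_benefit(100, 500, 100, 500).net_benefit == Decimal("0.00")

    def test_hand_arithmetic(self):
        result = net_benefit(200, 810, 160, 918)
        assert result.net_benefit == Decimal("148.00")

    @given(
        bf=st.integers(0, 1000), cf=st.integers(0, 2000),
        bw=st.integers(0, 1000), cw=st.integers(0, 2000),
        shift=st.integers(0, 500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_and_common_shift_invariance(self, bf, cf, bw, cw, shift):
        fwd = net_benefit(bf, cf, bw, cw).net_benefit
        rev = net_benefit(bw, cw, bf, cf).net_benefit
        assert fwd == -rev
        shifted = net_benefit(bf + shift, cf + shift, bw + shift, cw + shift)
        assert shifted.net_benefit == fwd


class TestConstructValidity:
    @staticmethod
    def paired(amount_sat_pairs, context=1):
        return [
            WTPResponse(f"p{i}", WEB, context, amount=a, satisfaction=s)
            for i, (a, s) in enumerate(amount_sat_pairs)
        ]

    def test_perfectly_monotone_gives_rho_one(self):
        rs = self.paired([(10, 1), (20, 2), (30, 3), (40, 4), (50, 5)])
        result = wtp_construct_validity(rs)[1]
        assert result.rho == pytest.approx(1.0)
        assert result.p_value <= 0.05

    def test_constant_satisfaction_is_undefined(self):
        rs = self.paired([(10, 3), (20, 3), (30, 3), (40, 3)])
        result = wtp_construct_validity(rs)[1]
        assert result.rho is None and result.p_value is None
        assert result.n == 4

    def test_fewer_than_three_pairs_is_empty_marker(self):
        rs = self.paired([(10, 1), (20, 2)])
        result = wtp_construct_validity(rs)[1]
        assert (result.n, result.rho) == (2, None)

    def test_tied_fixture_matches_hand_ranked_oracle(self):
        # amounts [10,20,20,30,40,50] -> ranks [1,2.5,2.5,4,5,6]
        # ratings [1,2,3,3,4,5]       -> ranks [1,2,3.5,3.5,5,6]
        # Pearson of the two rank vectors = 16.25/17
        rs = self.paired([(10, 1), (20, 2), (20, 3), (30, 3), (40, 4), (50, 5)])
        result = wtp_construct_validity(rs)[1]
        assert result.rho == pytest.approx(16.25 / 17)

    def test_missing_fields_dropped_per_context(self):
        rs = self.paired([(10, 1), (20, 2), (30, 3), (40, 4)]) + [
            WTPResponse("q1", WEB, 1, amount=99, satisfaction=None),
            WTPResponse("q2", WEB, 1, amount=None, satisfaction=5),
        ]
        assert wtp_construct_validity(rs)[1].n == 4

    def test_exact_permutation_p_matches_enumeration(self):
        # n=4 monotone: only 2 of 4! = 24 pairings reach |rho| = 1
        rs = [(10, 1), (20, 2), (30, 3), (40, 4)]
        result = spearman_validity(*zip(*rs), p_method="exact")
        assert result.p_value == pytest.approx(2 / 24)

    def test_exact_limited_to_small_n(self):
        x = list(range(12))
        with pytest.raises(ValueError):
            spearman_validity(x, x, p_method="exact")

    def test_asymptotic_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        result = spearman_validity(x, y, p_method="asymptotic")
        ref = stats.spearmanr(x, y)
        assert result.rho == pytest.approx(ref.statistic)
        assert result.p_value == pytest.approx(ref.pvalue)


class TestSensitivityTable:
    def test_published_web_column_cells(self):
        scenarios = [
            CBAScenario("primary"),
            CBAScenario("fees +50%", fee_scale=1.5),
            CBAScenario("all costs -50%", all_costs_scale=0.5),
            CBAScenario("satellite", internet_variant="satellite"),
        ]
        table = cba_sensitivity_table(scenarios)
        totals = dict(zip(table["scenario"], table["total_web"]))
        assert totals["primary"] == 918.0
        assert totals["fees +50%"] == 1043.0
        assert totals["all costs -50%"] == 459.0
        assert totals["satellite"] == 923.0

    def test_leisure_applies_penalty_to_both_arms(self):
        table = cba_sensitivity_table(
            [CBAScenario("primary"), CBAScenario("leisure", timing="leisure")]
        )
        primary, leisure = table.iloc[0], table.iloc[1]
        assert leisure["time_f2f"] == pytest.approx(primary["time_f2f"] * 1.5)
        assert leisure["time_web"] == pytest.approx(primary["time_web"] * 1.5)

    def test_service_paid_fee_leaves_participant_without_fee_component(self):
        table = cba_sensitivity_table(
            [CBAScenario("svc", fee_paid_by_participant=False)]
        )
        assert table.iloc[0]["fee_web"] == 0.0
        assert table.iloc[0]["total_web"] == pytest.approx(918.0 - 250.0)

    def test_net_benefit_column_from_benefit_means(self):
        table = cba_sensitivity_table(
            [CBAScenario("primary")],
            benefits={FACE_TO_FACE: Decimal("199"), WEB: Decimal("159.72")},
        )
        # (199 - 810) - (159.72 - 918) = 147.28
        assert table.iloc[0]["net_benefit"] == pytest.approx(147.28)
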