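"""Health-service-perspective cost-effectiveness analysis.

Effectiveness is measured in quality-adjusted students educated (QASE):
the number of completers weighted by the arm's average grade, with
non-completers contributing zero.  Service costs depend on when training
happens (working hours, unpaid study leave, or leisure time), whether the
service pays the enrollment fee, and whether replacement (backfill) staff
cover the trainee's duties.  Arms are compared with an incremental
cost-effectiveness ratio (Δcost / ΔQASE) with explicit dominance
handling.

Cost-assembly rules
-------------------
* Participant wages (with 17% on-costs) are charged whenever training
  displaces paid work — both the working-hours and unpaid-study-leave
  timings; leisure-time training costs the service nothing in wages.
* Backfill duplicates the wage term and is only coherent for
  working-hours timing.
* Transport and Internet downloads are participant-borne and never enter
  the service cost.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal
from typing import Mapping

import pandas as pd

from .money import money, round_cents
from .cost_model import FACE_TO_FACE, WEB, MODES, WagePolicy, wage_cost

WORKING_HOURS = "working_hours"
UNPAID_LEAVE = "unpaid_leave"
LEISURE = "leisure"
TIMINGS = (WORKING_HOURS, UNPAID_LEAVE, LEISURE)

#: timings under which participant wages are a cost to the service
_WAGE_BEARING_TIMINGS = (WORKING_HOURS, UNPAID_LEAVE)


@dataclass(frozen=True)
class QASERecord:
    """Enrollment, completion, and grade summary for one arm."""

    enrolled: int
    completers: int
    mean_grade: float  # fraction in [0, 1]

    def __post_init__(self):
        if self.enrolled < 0 or self.completers < 0:
            raise ValueError("counts must be >= 0")
        if self.completers > self.enrolled:
            raise ValueError("completers cannot exceed enrolled")
        if not 0.0 <= self.mean_grade <= 1.0:
            raise ValueError("mean_grade must be a fraction in [0, 1]")

    @property
    def qase(self) -> float:
        return qase(self.completers, self.mean_grade)


def qase(completers: int, mean_grade: float) -> float:
    """Quality-adjusted students educated: completers × mean grade.

    Non-completers are scored zero, so only the completer count enters.
    ``mean_grade`` is a fraction in [0, 1]; tables report QASE to two
    decimals.
    """
    if completers < 0:
        raise ValueError("completers must be >= 0")
    if not 0.0 <= mean_grade <= 1.0:
        raise ValueError("mean_grade must be a fraction in [0, 1]")
    return completers * mean_grade


@dataclass(frozen=True)
class CEAScenario:
    """One sensitivity-scenario configuration for the service cost.

    ``enrollment_fee`` and ``enrolled`` may be a single value applied to
    both arms or a per-arm mapping.  ``in_work_hours`` maps arm → hours of
    paid work displaced per participant.
    """

    label: str
    timing: str
    fee_paid_by_service: bool
    backfill: bool
    enrolled: object = 20
    enrollment_fee: object = Decimal("250")
    in_work_hours: Mapping = None
    wage_policy: WagePolicy = WagePolicy()

    def __post_init__(self):
        if self.timing not in TIMINGS:
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.backfill and self.timing != WORKING_HOURS:
            raise ValueError(
                "backfill is only meaningful when training occurs during "
                "working hours"
            )
        if self.in_work_hours is None:
            object.__setattr__(
                self, "in_work_hours", {FACE_TO_FACE: 8.0, WEB: 9.6}
            )

    def fee_for(self, arm: str) -> Decimal:
        if isinstance(self.enrollment_fee, Mapping):
            return money(self.enrollment_fee[arm])
        return money(self.enrollment_fee)

    def enrolled_for(self, arm: str) -> int:
        if isinstance(self.enrolled, Mapping):
            return int(self.enrolled[arm])
        return int(self.enrolled)


def service_cost(arm: str, scenario: CEAScenario) -> Decimal:
    """Assemble the health-service cost of one arm under a scenario.

    fee (if service-paid) + participant wages with on-costs (if training
    displaces work) + an equal backfill wage term (if flagged).
    """
    if arm not in MODES:
        raise ValueError(f"unknown arm {arm!r}")
    if arm not in scenario.in_work_hours:
        raise ValueError(f"no in-work hours configured for arm {arm!r}")
    n = scenario.enrolled_for(arm)
    total = Decimal("0")
    if scenario.fee_paid_by_service:
        total += scenario.fee_for(arm) * n
    if scenario.timing in _WAGE_BEARING_TIMINGS:
        per_head = wage_cost(
            scenario.in_work_hours[arm],
            scenario.wage_policy,
            apply_on_costs=True,
            apply_penalty=False,
        )
        total += per_head * n
        if scenario.backfill:
            total += per_head * n
    return round_cents(total)


EQUAL_COST = "equal cost — higher-QASE arm preferred"
DOMINANT = "dominant — cheaper at no QASE loss"
EQUIVALENT = "equivalent — identical cost and QASE"


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of two arms (first minus second).

    ``ratio`` is Δcost/ΔQASE when defined.  Degenerate cases carry a
    ``dominance`` marker: equal costs report a ratio of 0 with the
    higher-QASE arm preferred; equal QASE at unequal cost reports the
    cheaper arm as dominant with no finite ratio.
    """

    delta_cost: Decimal
    delta_effect: float
    ratio: float | None
    preferred_arm: str | None
    dominance: str | None = None


def icer(
    cost_a,
    cost_b,
    qase_a: float,
    qase_b: float,
    arms: tuple = (FACE_TO_FACE, WEB),
) -> ICERResult:
    """Incremental cost-effectiveness ratio of arm a over arm b."""
    delta_cost = round_cents(money(cost_a) - money(cost_b))
    delta_effect = qase_a - qase_b
    if delta_cost == 0 and delta_effect == 0:
        return ICERResult(delta_cost, delta_effect, 0.0, None, EQUIVALENT)
    if delta_cost == 0:
        preferred = arms[0] if delta_effect > 0 else arms[1]
        return ICERResult(delta_cost, delta_effect, 0.0, preferred, EQUAL_COST)
    if delta_effect == 0:
        preferred = arms[0] if delta_cost < 0 else arms[1]
        return ICERResult(delta_cost, delta_effect, None, preferred, DOMINANT)
    ratio = float(delta_cost) / delta_effect
    # strict dominance: cheaper and more effective
    if delta_cost < 0 and delta_effect > 0:
        preferred, dominance = arms[0], DOMINANT
    elif delta_cost > 0 and delta_effect < 0:
        preferred, dominance = arms[1], DOMINANT
    else:
        preferred, dominance = None, None
    return ICERResult(delta_cost, delta_effect, ratio, preferred, dominance)


def cea_sensitivity_table(
    arms: Mapping[str, QASERecord],
    scenarios,
    include_equal_attrition: bool = True,
    alternative_fee_factor: float | None = 2.1,
) -> pd.DataFrame:
    """Tabulate service costs, QASE, and ICERs across scenarios.

    ``arms`` maps the two delivery modes to their :class:`QASERecord`.
    Two derived variants are appended, both based on the *first* scenario
    (conventionally the primary one):

    * equal attrition — the web arm's completers forced equal to
      face-to-face, isolating the grade difference;
    * alternative fee — the face-to-face fee inflated by
      ``alternative_fee_factor`` (default 2.1, i.e. $525 from a $250
      base) with the service paying fees.
    """
    if set(arms) != set(MODES):
        raise ValueError(f"arms must be exactly {set(MODES)}")
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("at least one scenario required")

    records = dict(arms)
    rows = []

    def add_row(label, scenario, recs):
        costs = {arm: service_cost(arm, scenario) for arm in MODES}
        q = {arm: recs[arm].qase for arm in MODES}
        result = icer(
            costs[FACE_TO_FACE], costs[WEB], q[FACE_TO_FACE], q[WEB]
        )
        rows.append(
            {
                "scenario": label,
                "timing": scenario.timing,
                "fee_paid_by_service": scenario.fee_paid_by_service,
                "backfill": scenario.backfill,
                "cost_f2f": float(costs[FACE_TO_FACE]),
                "cost_web": float(costs[WEB]),
                "qase_f2f": round(q[FACE_TO_FACE], 2),
                "qase_web": round(q[WEB], 2),
                "icer": result.ratio,
                "preferred_arm": result.preferred_arm,
                "dominance": result.dominance,
            }
        )

    for scenario in scenarios:
        add_row(scenario.label, scenario, records)

    primary = scenarios[0]
    if include_equal_attrition:
        equal = dict(records)
        equal[WEB] = replace(
            records[WEB], completers=records[FACE_TO_FACE].completers
        )
        add_row(f"{primary.label} — equal attrition", primary, equal)
    if alternative_fee_factor is not None:
        base_fee = primary.fee_for(FACE_TO_FACE)
        alt_fee = {
            FACE_TO_FACE: round_cents(base_fee * money(alternative_fee_factor)),
            WEB: primary.fee_for(WEB),
        }
        alt = replace(primary, enrollment_fee=alt_fee, fee_paid_by_service=True)
        add_row(f"{primary.label} — alternative f2f fee", alt, records)

    return pd.DataFrame(rows)
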