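"""Itemized cost structures, wage policy, and time profiles.

Every perspective-specific analysis (provider break-even, health-service
cost-effectiveness, participant cost-benefit) assembles its costs from the
primitives here: itemized per-class fixed and per-participant variable
costs, an hourly wage policy with employer on-costs and out-of-hours
penalty loading, and the contact/total time profiles of the two delivery
modes.

Conventions
-----------
* Fixed costs recur *per class delivered*: once enrollments exceed the
  class capacity a second class opens and the full fixed cost is incurred
  again (:func:`cumulative_fixed_cost`).
* Wages are valued at a flat hourly rate (default AUD $45, an early-career
  allied-health award rate).  Employer perspectives add 17% on-costs;
  out-of-hours participation adds time-and-a-half penalty loading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Sequence

from .money import money, round_cents

# Enumerations ---------------------------------------------------------------

PER_CLASS_FIXED = "per-class-fixed"
PER_PARTICIPANT_VARIABLE = "per-participant-variable"
RECURRENCES = (PER_CLASS_FIXED, PER_PARTICIPANT_VARIABLE)

PAYERS = ("provider", "health_service", "participant")

FACE_TO_FACE = "face_to_face"
WEB = "web"
MODES = (FACE_TO_FACE, WEB)


@dataclass(frozen=True)
class CostItem:
    """One line of a delivery-mode cost structure.

    Parameters
    ----------
    name : str
        Short label ("venue", "catering", ...).
    amount : money
        Non-negative AUD amount, exact to cents.
    recurrence : {"per-class-fixed", "per-participant-variable"}
        Whether the item recurs per class delivered or per enrollee.
    payer : {"provider", "health_service", "participant"}
        Who bears the item in the primary configuration.
    """

    name: str
    amount: Decimal
    recurrence: str
    payer: str = "provider"

    def __post_init__(self):
        object.__setattr__(self, "amount", money(self.amount))
        if self.amount < 0:
            raise ValueError(f"cost item {self.name!r}: amount must be >= 0")
        if self.recurrence not in RECURRENCES:
            raise ValueError(
                f"cost item {self.name!r}: unknown recurrence {self.recurrence!r}"
            )
        if self.payer not in PAYERS:
            raise ValueError(f"cost item {self.name!r}: unknown payer {self.payer!r}")


@dataclass(frozen=True)
class WagePolicy:
    """Hourly wage valuation: base rate, on-costs, penalty loading.

    ``base_rate`` is the AUD hourly wage used as the opportunity cost of
    time.  ``on_cost_multiplier`` (default 1.17, i.e. 17% on-costs) applies
    for employer perspectives; ``penalty_loading`` (default 1.5,
    time-and-a-half) applies for out-of-hours participation.
    """

    base_rate: Decimal = Decimal("45")
    on_cost_multiplier: Decimal = Decimal("1.17")
    penalty_loading: Decimal = Decimal("1.5")

    def __post_init__(self):
        object.__setattr__(self, "base_rate", money(self.base_rate))
        object.__setattr__(self, "on_cost_multiplier", money(self.on_cost_multiplier))
        object.__setattr__(self, "penalty_loading", money(self.penalty_loading))
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.on_cost_multiplier < 1:
            raise ValueError("on_cost_multiplier must be >= 1")
        if self.penalty_loading < 1:
            raise ValueError("penalty_loading must be >= 1")


@dataclass(frozen=True)
class TimeProfile:
    """Hours committed per participant, by delivery mode and perspective.

    The employer (CEA) perspective uses in-work contact hours: 8 for
    face-to-face and ``8 + extra_hours_web`` for web.  The participant
    (CBA) perspective uses total time on task, which is configured
    independently because self-reported totals exceed contact hours.
    """

    contact_hours_f2f: float = 8.0
    extra_hours_web: float = 1.6
    participant_total_hours_f2f: float = 12.0
    participant_total_hours_web: float = 14.4

    def __post_init__(self):
        for name in (
            "contact_hours_f2f",
            "extra_hours_web",
            "participant_total_hours_f2f",
            "participant_total_hours_web",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.extra_hours_web > 0:
            if self.participant_total_hours_web < self.participant_total_hours_f2f:
                raise ValueError(
                    "web participant hours must be >= face-to-face when web "
                    "contact time is longer"
                )

    @property
    def contact_hours_web(self) -> float:
        return self.contact_hours_f2f + self.extra_hours_web

    def in_work_hours(self) -> dict:
        return {FACE_TO_FACE: self.contact_hours_f2f, WEB: self.contact_hours_web}

    def participant_hours(self) -> dict:
        return {
            FACE_TO_FACE: self.participant_total_hours_f2f,
            WEB: self.participant_total_hours_web,
        }


@dataclass(frozen=True)
class DeliveryCostStructure:
    """Full itemized cost structure for one delivery mode.

    ``items`` must contain the facilitator contract (``facilitator_hours``
    × ``facilitator_rate``) as one of its per-class-fixed lines; the two
    facilitator fields exist so sensitivity sweeps can rebuild the fixed
    total when the contract changes.
    """

    mode: str
    items: tuple
    class_capacity: int
    facilitator_hours: float
    facilitator_rate: Decimal

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown delivery mode {self.mode!r}")
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ValueError("cost structure needs at least one item")
        if self.class_capacity < 1:
            raise ValueError("class_capacity must be >= 1")
        if self.facilitator_hours < 0:
            raise ValueError("facilitator_hours must be >= 0")
        object.__setattr__(self, "facilitator_rate", money(self.facilitator_rate))
        if self.facilitator_rate < 0:
            raise ValueError("facilitator_rate must be >= 0")

    @property
    def fixed_total(self) -> Decimal:
        return fixed_and_variable_totals(self)[0]

    @property
    def variable_total(self) -> Decimal:
        return fixed_and_variable_totals(self)[1]

    @property
    def facilitator_cost(self) -> Decimal:
        return round_cents(money(self.facilitator_hours) * self.facilitator_rate)

    @property
    def other_fixed(self) -> Decimal:
        """Fixed costs excluding the facilitator contract."""
        other = self.fixed_total - self.facilitator_cost
        if other < 0:
            raise ValueError(
                "facilitator contract exceeds the fixed total; the contract "
                "must be included inside items"
            )
        return other


# Operations -----------------------------------------------------------------


def wage_cost(
    hours,
    policy: WagePolicy | None = None,
    apply_on_costs: bool = False,
    apply_penalty: bool = False,
) -> Decimal:
    """Value a number of hours at the wage policy, exact to cents.

    ``hours × base_rate``, multiplied by the 17% on-cost factor and/or the
    time-and-a-half penalty loading when the corresponding flag is set.
    """
    if policy is None:
        policy = WagePolicy()
    if hours < 0:
        raise ValueError("hours must be >= 0")
    total = money(hours) * policy.base_rate
    if apply_on_costs:
        total *= policy.on_cost_multiplier
    if apply_penalty:
        total *= policy.penalty_loading
    return round_cents(total)


def fixed_and_variable_totals(
    structure: "DeliveryCostStructure | Iterable[CostItem]",
) -> tuple:
    """Sum a cost structure into (per-class fixed, per-participant variable).

    Order-invariant; raises on an unknown recurrence tag.
    """
    items: Sequence[CostItem]
    if isinstance(structure, DeliveryCostStructure):
        items = structure.items
    else:
        items = tuple(structure)
    if not items:
        raise ValueError("cost structure needs at least one item")
    fixed = Decimal("0")
    variable = Decimal("0")
    for item in items:
        if item.recurrence == PER_CLASS_FIXED:
            fixed += item.amount
        elif item.recurrence == PER_PARTICIPANT_VARIABLE:
            variable += item.amount
        else:  # pragma: no cover - CostItem validates, kept for raw tuples
            raise ValueError(f"unknown recurrence tag {item.recurrence!r}")
    return round_cents(fixed), round_cents(variable)


def cumulative_fixed_cost(enrollments: int, fixed_per_class, capacity: int) -> Decimal:
    """Total fixed cost once ``enrollments`` students are spread over classes.

    Fixed costs replicate each time a class fills: the total is
    ``fixed_per_class × ceil(enrollments / capacity)`` (zero when nobody
    enrolls and no class opens).
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    if enrollments < 0:
        raise ValueError("enrollments must be >= 0")
    if enrollments == 0:
        return Decimal("0.00")
    classes = math.ceil(enrollments / capacity)
    return round_cents(money(fixed_per_class) * classes)
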