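"""Provider-perspective break-even analysis with stepped fixed costs.

A course breaks even when cumulative fee revenue covers cumulative costs.
With per-class fixed costs that replicate each time a class fills to
capacity, the net position is a sawtooth in the enrollment count and a
course can break even, dip back into loss when the next class opens, and
break even again — hence profitability is reported as *segments* of the
integer enrollment domain rather than a single point.

Two solver conventions are provided:

* :func:`breakeven_segments` — exhaustive integer scan; mathematically
  exact, returns every maximal run of non-negative net position (a net of
  exactly zero counts as break-even).
* :func:`breakeven_rounded_ratio` — the classic single-class textbook
  ratio ``Q = FC / (S − VC)`` rounded half-up to the nearest integer.
  This reproduces headline single-number break-even points quoted from
  the ratio; it can disagree with the exact scan by one enrollee when the
  ratio's fractional part is below one half.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP

from .money import money, round_cents
from .cost_model import cumulative_fixed_cost

SWEEP_AXES = (
    "facilitator_hours",
    "facilitator_rate",
    "class_capacity",
    "enrollment_fee",
    "all_costs_scale",
)


@dataclass(frozen=True)
class BreakEvenScenario:
    """One break-even configuration.

    ``fixed_per_class`` (FC) recurs per class of ``class_capacity``;
    ``variable_per_participant`` (VC) and ``enrollment_fee`` (S, the
    saving per enrollee) accrue per participant.  The scan covers
    enrollments 1..``max_enrollments``.
    """

    fixed_per_class: Decimal
    variable_per_participant: Decimal
    enrollment_fee: Decimal
    class_capacity: int
    max_enrollments: int = 60

    def __post_init__(self):
        for name in ("fixed_per_class", "variable_per_participant", "enrollment_fee"):
            object.__setattr__(self, name, money(getattr(self, name)))
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.class_capacity < 1:
            raise ValueError("class_capacity must be >= 1")
        if self.max_enrollments < 1:
            raise ValueError("max_enrollments must be >= 1")

    @property
    def margin(self) -> Decimal:
        """Contribution margin S − VC per enrollee."""
        return self.enrollment_fee - self.variable_per_participant


@dataclass(frozen=True)
class ProfitabilitySegments:
    """Maximal enrollment intervals with non-negative net position.

    ``segments`` is a sorted tuple of inclusive ``(start, end)`` intervals
    within ``[1, max_enrollments]``; empty when the course never breaks
    even in range.
    """

    segments: tuple
    max_enrollments: int

    def __post_init__(self):
        object.__setattr__(
            self, "segments", tuple((int(a), int(b)) for a, b in self.segments)
        )
        prev_end = None
        for a, b in self.segments:
            if not (1 <= a <= b <= self.max_enrollments):
                raise ValueError(f"segment ({a}, {b}) out of range")
            if prev_end is not None:
                if a <= prev_end:
                    raise ValueError("segments must be disjoint and sorted")
                if a == prev_end + 1:
                    # touching segments would not be maximal runs
                    raise ValueError("adjacent segments must be merged")
            prev_end = b

    @property
    def breaks_even(self) -> bool:
        return bool(self.segments)

    @property
    def first_break_even(self) -> int | None:
        """Smallest enrollment count with non-negative net, or None."""
        return self.segments[0][0] if self.segments else None

    def contains(self, enrollments: int) -> bool:
        return any(a <= enrollments <= b for a, b in self.segments)

    def __str__(self) -> str:
        if not self.segments:
            return "does not break even"
        parts = []
        for a, b in self.segments:
            parts.append(str(a) if a == b else f"{a}–{b}")
        return "; ".join(parts)


def net_position(enrollments: int, scenario: BreakEvenScenario) -> Decimal:
    """Cumulative net position at a given enrollment count.

    ``enrollments × (S − VC) − FC × ceil(enrollments / capacity)``; zero
    at zero enrollments (no class opened).
    """
    if not 0 <= enrollments <= scenario.max_enrollments:
        raise ValueError(
            f"enrollments must be in [0, {scenario.max_enrollments}]"
        )
    revenue_net_of_variable = scenario.margin * enrollments
    fixed = cumulative_fixed_cost(
        enrollments, scenario.fixed_per_class, scenario.class_capacity
    )
    return round_cents(revenue_net_of_variable - fixed)


def breakeven_segments(scenario: BreakEvenScenario) -> ProfitabilitySegments:
    """Exact integer-scan solver.

    Scans q = 1..max_enrollments and returns the maximal runs where
    ``net_position(q) >= 0``.  Deterministic and exact; a net of exactly
    zero counts as breaking even.
    """
    segments = []
    start = None
    for q in range(1, scenario.max_enrollments + 1):
        if net_position(q, scenario) >= 0:
            if start is None:
                start = q
        else:
            if start is not None:
                segments.append((start, q - 1))
                start = None
    if start is not None:
        segments.append((start, scenario.max_enrollments))
    return ProfitabilitySegments(tuple(segments), scenario.max_enrollments)


def breakeven_rounded_ratio(scenario: BreakEvenScenario) -> int | None:
    """Legacy single-class break-even: FC/(S − VC) rounded half-up.

    Returns None when the margin is non-positive (every enrollment loses
    money).  Ignores capacity stepping — this is the headline textbook
    number, not the exact scan.
    """
    if scenario.margin <= 0:
        return None
    ratio = scenario.fixed_per_class / scenario.margin
    return int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FacilitatorTerms:
    """Decomposition of FC for facilitator sweeps: hours × rate + other."""

    hours: float
    rate: Decimal
    other_fixed: Decimal

    def __post_init__(self):
        object.__setattr__(self, "rate", money(self.rate))
        object.__setattr__(self, "other_fixed", money(self.other_fixed))

    def fixed_per_class(self) -> Decimal:
        return round_cents(money(self.hours) * self.rate + self.other_fixed)


@dataclass(frozen=True)
class SweepRow:
    """One row of a one-way sensitivity sweep."""

    axis: str
    value: object
    scenario: BreakEvenScenario
    segments: ProfitabilitySegments
    rounded_ratio: int | None


def _scenario_for(base, axis, value, facilitator):
    if axis in ("facilitator_hours", "facilitator_rate"):
        if facilitator is None:
            raise ValueError(
                f"axis {axis!r} requires FacilitatorTerms (hours, rate, other fixed)"
            )
        if axis == "facilitator_hours":
            terms = replace(facilitator, hours=float(value))
        else:
            terms = replace(facilitator, rate=money(value))
        return replace(base, fixed_per_class=terms.fixed_per_class())
    if axis == "class_capacity":
        return replace(base, class_capacity=int(value))
    if axis == "enrollment_fee":
        return replace(base, enrollment_fee=money(value))
    if axis == "all_costs_scale":
        scale = money(value)
        return replace(
            base,
            fixed_per_class=round_cents(base.fixed_per_class * scale),
            variable_per_participant=round_cents(
                base.variable_per_participant * scale
            ),
        )
    raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")


def sensitivity_sweep(
    base: BreakEvenScenario,
    axis: str,
    values,
    facilitator: FacilitatorTerms | None = None,
) -> list:
    """One-way sensitivity sweep over a single parameter axis.

    One :class:`SweepRow` per value, all other parameters held at
    ``base``.  Facilitator axes rebuild FC as ``hours × rate +
    other_fixed``; ``all_costs_scale`` multiplies FC and VC jointly.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
    rows = []
    for value in values:
        scenario = _scenario_for(base, axis, value, facilitator)
        rows.append(
            SweepRow(
                axis=axis,
                value=value,
                scenario=scenario,
                segments=breakeven_segments(scenario),
                rounded_ratio=breakeven_rounded_ratio(scenario),
            )
        )
    return rows


def breakeven_curve(scenario: BreakEvenScenario):
    """Cost and savings series over the enrollment domain.

    Returns a DataFrame with one row per enrollment count 0..max:
    cumulative cost (fixed + variable), cumulative savings (fee revenue),
    and the net position — the data behind a cost-vs-savings plot.
    """
    import pandas as pd

    rows = []
    for q in range(scenario.max_enrollments + 1):
        fixed = cumulative_fixed_cost(
            q, scenario.fixed_per_class, scenario.class_capacity
        )
        cost = fixed + scenario.variable_per_participant * q
        savings = scenario.enrollment_fee * q
        rows.append(
            {
                "enrollments": q,
                "cost": float(round_cents(cost)),
                "savings": float(round_cents(savings)),
                "net": float(round_cents(savings - cost)),
            }
        )
    return pd.DataFrame(rows)
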