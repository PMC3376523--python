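"""Participant-perspective cost-benefit analysis.

Costs are the out-of-pocket and time expenses a participant incurs
(Internet downloads for the web mode, car transport for face-to-face, the
enrollment fee, and time valued at the hourly wage *without* employer
on-costs).  Benefit is the stated maximum willingness to pay (WTP) for
the course, elicited under four recognition contexts.  The two arms are
compared with a net-benefit difference, and the construct validity of the
WTP responses is checked by rank-correlating them with overall course
satisfaction (Spearman rho).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .money import money, round_cents
from .cost_model import FACE_TO_FACE, WEB, MODES, WagePolicy, wage_cost
from .cea import TIMINGS, LEISURE

WTP_CONTEXTS = (1, 2, 3, 4)

BROADBAND = "broadband"
SATELLITE = "satellite"
INTERNET_VARIANTS = (BROADBAND, SATELLITE)

#: default out-of-pocket constants (AUD)
DOWNLOAD_COST = {BROADBAND: Decimal("20"), SATELLITE: Decimal("25")}
TRANSPORT_COST = Decimal("20")


@dataclass(frozen=True)
class ParticipantExpense:
    """Itemized expense for one participant; total is the exact sum."""

    downloads: Decimal
    transport: Decimal
    fee: Decimal
    time_cost: Decimal

    def __post_init__(self):
        for name in ("downloads", "transport", "fee", "time_cost"):
            object.__setattr__(self, name, round_cents(getattr(self, name)))

    @property
    def total(self) -> Decimal:
        return round_cents(
            self.downloads + self.transport + self.fee + self.time_cost
        )

    def scaled(self, factor) -> "ParticipantExpense":
        """Every component scaled by ``factor`` (all-costs sensitivity)."""
        k = money(factor)
        return ParticipantExpense(
            self.downloads * k, self.transport * k, self.fee * k, self.time_cost * k
        )


def participant_expense(
    arm: str,
    fee,
    time_hours: float,
    policy: WagePolicy | None = None,
    timing: str = "working_hours",
    internet_variant: str = BROADBAND,
    download_costs: Mapping = DOWNLOAD_COST,
    transport_cost=TRANSPORT_COST,
) -> ParticipantExpense:
    """Assemble one participant's expenses for a delivery mode.

    The web mode incurs the Internet download cost (broadband or the
    dearer satellite variant); face-to-face incurs car transport.  Time is
    valued at the base wage — no on-costs from the participant's
    perspective — with time-and-a-half penalty loading when the course
    occupies leisure time.
    """
    if arm not in MODES:
        raise ValueError(f"unknown arm {arm!r}")
    if timing not in TIMINGS:
        raise ValueError(f"unknown timing {timing!r}")
    if internet_variant not in download_costs:
        raise ValueError(f"unknown internet variant {internet_variant!r}")
    if money(fee) < 0 or time_hours < 0:
        raise ValueError("fee and time_hours must be >= 0")
    if policy is None:
        policy = WagePolicy()
    downloads = money(download_costs[internet_variant]) if arm == WEB else Decimal("0")
    transport = money(transport_cost) if arm == FACE_TO_FACE else Decimal("0")
    time_cost = wage_cost(
        time_hours, policy, apply_on_costs=False, apply_penalty=(timing == LEISURE)
    )
    return ParticipantExpense(downloads, transport, money(fee), time_cost)


# Willingness to pay ---------------------------------------------------------


@dataclass(frozen=True)
class WTPResponse:
    """One participant's stated WTP for one recognition context."""

    participant_id: str
    arm: str
    context: int
    amount: Decimal | None = None
    satisfaction: int | None = None

    def __post_init__(self):
        if self.arm not in MODES:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.context not in WTP_CONTEXTS:
            raise ValueError(f"context must be one of {WTP_CONTEXTS}")
        if self.amount is not None:
            object.__setattr__(self, "amount", money(self.amount))
            if self.amount < 0:
                raise ValueError("WTP amount must be >= 0")


@dataclass(frozen=True)
class WTPSummary:
    """n / mean / SD of non-missing WTP; mean and SD are None markers
    when undefined (no responses; a single response has no sample SD)."""

    n: int
    mean: Decimal | None
    sd: Decimal | None

    @property
    def empty(self) -> bool:
        return self.n == 0


def mean_wtp(
    responses: Iterable[WTPResponse], arm: str, context: int
) -> WTPSummary:
    """Arithmetic mean and sample SD of stated WTP for one arm/context.

    Missing amounts are dropped (respondent counts vary by context);
    no non-missing responses yields an empty-result marker rather than
    an exception.
    """
    if context not in WTP_CONTEXTS:
        raise ValueError(f"context must be one of {WTP_CONTEXTS}")
    amounts = [
        float(r.amount)
        for r in responses
        if r.arm == arm and r.context == context and r.amount is not None
    ]
    if not amounts:
        return WTPSummary(0, None, None)
    mean = round_cents(sum(money(a) for a in amounts) / len(amounts))
    if len(amounts) == 1:
        return WTPSummary(1, mean, None)
    sd = round_cents(float(np.std(amounts, ddof=1)))
    return WTPSummary(len(amounts), mean, sd)


def responses_from_table(table: pd.DataFrame) -> list:
    """Flatten a participant-level table into :class:`WTPResponse` rows.

    Expects columns ``id, arm, wtp_c1..wtp_c4, satisfaction``; NaN maps
    to a missing amount/rating.
    """
    out = []
    for row in table.itertuples(index=False):
        sat = getattr(row, "satisfaction", None)
        sat = None if sat is None or pd.isna(sat) else int(sat)
        for context in WTP_CONTEXTS:
            raw = getattr(row, f"wtp_c{context}")
            amount = None if pd.isna(raw) else money(float(raw))
            out.append(
                WTPResponse(
                    participant_id=str(row.id),
                    arm=row.arm,
                    context=context,
                    amount=amount,
                    satisfaction=sat,
                )
            )
    return out


# Net benefit ----------------------------------------------------------------


@dataclass(frozen=True)
class NetBenefitResult:
    """Between-arm net benefit; positive favors face-to-face."""

    benefit_f2f: Decimal
    cost_f2f: Decimal
    benefit_web: Decimal
    cost_web: Decimal

    def __post_init__(self):
        for name in ("benefit_f2f", "cost_f2f", "benefit_web", "cost_web"):
            object.__setattr__(self, name, round_cents(getattr(self, name)))

    @property
    def net_benefit(self) -> Decimal:
        return round_cents(
            (self.benefit_f2f - self.cost_f2f)
            - (self.benefit_web - self.cost_web)
        )


def net_benefit(benefit_f2f, cost_f2f, benefit_web, cost_web) -> NetBenefitResult:
    """(benefit − cost) of face-to-face minus (benefit − cost) of web."""
    return NetBenefitResult(
        money(benefit_f2f), money(cost_f2f), money(benefit_web), money(cost_web)
    )


# Construct validity ---------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    """Rank correlation for one context; rho/p are None markers when the
    correlation is undefined (fewer than 3 pairs, or zero rank variance)."""

    n: int
    rho: float | None
    p_value: float | None


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (pairings permuted).

    Enumerates all n! pairings of the rank vectors; feasible for n <= 10.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    denom = math.sqrt(float(rxc @ rxc))
    count = total = 0
    target = abs(rho_obs) - 1e-12
    for perm in permutations(ry):
        ryc = np.asarray(perm) - ry.mean()
        r = float(rxc @ ryc) / (denom * math.sqrt(float(ryc @ ryc)))
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman_validity(
    amounts: Sequence[float],
    satisfaction: Sequence[float],
    p_method: str = "auto",
) -> SpearmanResult:
    """Spearman rho (average-rank ties) with a two-sided p-value.

    ``p_method``: ``"asymptotic"`` (large-sample t approximation via
    scipy), ``"exact"`` (full permutation enumeration, n <= 10), or
    ``"auto"`` (exact when n <= 8, else asymptotic).
    """
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(satisfaction, dtype=float)
    n = len(x)
    if n < 3:
        return SpearmanResult(n, None, None)
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        # zero rank variance: correlation undefined
        return SpearmanResult(n, None, None)
    rho, p_asym = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        return SpearmanResult(n, None, None)
    if p_method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown p_method {p_method!r}")
    use_exact = p_method == "exact" or (p_method == "auto" and n <= 8)
    if use_exact:
        if n > 10:
            raise ValueError("exact permutation p is limited to n <= 10")
        p = _exact_permutation_p(x, y, float(rho))
    else:
        p = float(p_asym)
    return SpearmanResult(n, float(rho), p)


def wtp_construct_validity(
    responses: Iterable[WTPResponse], p_method: str = "auto"
) -> dict:
    """Per-context rank correlation between WTP and course satisfaction.

    Pools both arms; pairs missing either field are dropped per context.
    Contexts with fewer than 3 complete pairs get an empty-result marker.
    """
    responses = list(responses)
    out = {}
    for context in WTP_CONTEXTS:
        pairs = [
            (float(r.amount), r.satisfaction)
            for r in responses
            if r.context == context
            and r.amount is not None
            and r.satisfaction is not None
        ]
        if len(pairs) < 3:
            out[context] = SpearmanResult(len(pairs), None, None)
            continue
        amounts, sats = zip(*pairs)
        out[context] = spearman_validity(amounts, sats, p_method=p_method)
    return out


# Sensitivity table ----------------------------------------------------------


@dataclass(frozen=True)
class CBAScenario:
    """One participant-expense sensitivity configuration.

    ``fee_scale`` and ``all_costs_scale`` are multiplicative; expenses are
    always recomputed from components, never by scaling printed totals.
    ``fee_override`` replaces the base fee per arm (the alternative fee
    structure); ``fee_paid_by_participant=False`` drops the fee from the
    participant's expense (the service pays it).
    """

    label: str
    timing: str = "working_hours"
    internet_variant: str = BROADBAND
    fee_scale: float = 1.0
    all_costs_scale: float = 1.0
    fee_paid_by_participant: bool = True
    fee_override: Mapping | None = None

    def __post_init__(self):
        if self.timing not in TIMINGS:
            raise ValueError(f"unknown timing {self.timing!r}")
        if self.internet_variant not in INTERNET_VARIANTS:
            raise ValueError(f"unknown internet variant {self.internet_variant!r}")


def cba_sensitivity_table(
    scenarios: Sequence[CBAScenario],
    fee=Decimal("250"),
    time_hours: Mapping | None = None,
    policy: WagePolicy | None = None,
    benefits: Mapping | None = None,
) -> pd.DataFrame:
    """Recompute participant expenses and net benefit per scenario.

    ``time_hours`` maps arm → participant hours (defaults 12 f2f /
    14.4 web).  ``benefits`` optionally maps arm → mean WTP (the benefit
    proxy); when given, each row carries the net-benefit difference
    (positive favors face-to-face).
    """
    if time_hours is None:
        time_hours = {FACE_TO_FACE: 12.0, WEB: 14.4}
    rows = []
    for sc in scenarios:
        expenses = {}
        for arm in MODES:
            base_fee = money(
                sc.fee_override[arm] if sc.fee_override is not None else fee
            )
            arm_fee = round_cents(base_fee * money(sc.fee_scale))
            if not sc.fee_paid_by_participant:
                arm_fee = Decimal("0")
            expense = participant_expense(
                arm,
                arm_fee,
                time_hours[arm],
                policy=policy,
                timing=sc.timing,
                internet_variant=sc.internet_variant,
            )
            if sc.all_costs_scale != 1.0:
                expense = expense.scaled(sc.all_costs_scale)
            expenses[arm] = expense
        row = {"scenario": sc.label, "timing": sc.timing}
        for arm, short in ((WEB, "web"), (FACE_TO_FACE, "f2f")):
            e = expenses[arm]
            row.update(
                {
                    f"downloads_{short}": float(e.downloads),
                    f"transport_{short}": float(e.transport),
                    f"fee_{short}": float(e.fee),
                    f"time_{short}": float(e.time_cost),
                    f"total_{short}": float(e.total),
                }
            )
        if benefits is not None:
            nb = net_benefit(
                benefits[FACE_TO_FACE],
                expenses[FACE_TO_FACE].total,
                benefits[WEB],
                expenses[WEB].total,
            )
            row["net_benefit"] = float(nb.net_benefit)
        rows.append(row)
    return pd.DataFrame(rows)
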