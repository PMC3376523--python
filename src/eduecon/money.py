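"""Exact-cents currency arithmetic.

All monetary quantities in the package are AUD ``Decimal`` values.  Costs
and fees are carried exactly; rounding to cents (half-up, the bookkeeping
convention) happens once, at each operation's return boundary, never
mid-expression.  Binary floating point is never used for money.
"""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")

MoneyLike = "Decimal | int | float | str"


def money(value) -> Decimal:
    """Coerce a number to an exact ``Decimal``.

    Floats are routed through ``str`` so that e.g. ``money(1.17)`` is
    exactly ``Decimal("1.17")`` rather than the nearest binary fraction.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(str(value))
    return Decimal(value)


def round_cents(value) -> Decimal:
    """Round a monetary amount to cents, half-up."""
    return money(value).quantize(CENT, rounding=ROUND_HALF_UP)


def fmt_money(value) -> str:
    """Render with exactly two decimals (plain AUD numerics, no symbol)."""
    return f"{round_cents(value):.2f}"
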