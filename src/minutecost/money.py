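"""Currency helpers.

Ledger amounts are held as integer cents; floats appear only in derived
quantities (per-person costs, ratios).  Report rounding is half-up, the
convention used in accounting, not Python's default banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["to_cents", "from_cents", "round_cents", "round_dollars"]


def to_cents(dollars: float) -> int:
    """Convert a dollar amount to integer cents, rounding half-up."""
    return int(Decimal(repr(float(dollars))).scaleb(2).quantize(Decimal("1"), ROUND_HALF_UP))


def from_cents(cents: int) -> float:
    """Integer cents back to a float dollar amount."""
    return cents / 100.0


def round_cents(x: float) -> float:
    """Round a dollar amount to cents (half-up)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def round_dollars(x: float) -> int:
    """Round a dollar amount to whole dollars (half-up)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), ROUND_HALF_UP))
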