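"""Half-up rounding and number formatting for reported figures."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_up", "format_trimmed"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reported tables use half-up, not banker's)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_trimmed(x: float, ndigits: int) -> str:
    """Format to ``ndigits`` decimals, trimming trailing zeros ('97.00' -> '97')."""
    text = f"{round_half_up(x, ndigits):.{ndigits}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text
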