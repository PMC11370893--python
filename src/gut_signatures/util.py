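"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (not banker's rounding).

    Printed percentages in the compiled tables follow this convention
    (e.g. 84.615 -> 84.6, 65.4545 -> 65.5, 7.2727 -> 7.3).
    """
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total`` rounded half-away-from-zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, ndigits)
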