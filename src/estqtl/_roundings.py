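"""Half-away-from-zero decimal rounding for printed percentages and rates."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed report tables).

    Python's built-in ``round`` is banker's rounding; report tables round
    0.05 -> 0.1, so this goes through ``decimal`` with ROUND_HALF_UP.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
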