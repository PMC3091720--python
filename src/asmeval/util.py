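"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (printed-table convention).

    Python's built-in ``round`` rounds half to even; reported tables use
    the everyday rule where 64.95 -> 65.0 and 676.7 -> 677.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
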