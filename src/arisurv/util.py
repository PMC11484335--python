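"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent_change"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's built-in ``round`` uses banker's rounding; reporting here uses
    half-up, applied only at presentation time.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_change(old_value: float, new_value: float) -> float:
    """Signed percentage change from *old_value* to *new_value*, one decimal.

    ``100 * (new - old) / old`` rounded half-up to one decimal place.

    Raises
    ------
    ValueError
        If ``old_value`` is not strictly positive.
    """
    if old_value <= 0:
        raise ValueError(
            f"percent change is undefined for non-positive baseline {old_value!r}"
        )
    return round_half_up(100.0 * (new_value - old_value) / old_value, 1)
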