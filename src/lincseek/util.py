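"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (3.25 -> 3.3 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(value: float, decimals: int = 1, small_decimals: int | None = 2) -> float:
    """Round a percentage; values below 10 get ``small_decimals`` places."""
    if small_decimals is not None and value < 10:
        return round_half_up(value, small_decimals)
    return round_half_up(value, decimals)
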