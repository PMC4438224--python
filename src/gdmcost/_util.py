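"""Small shared helpers (display rounding, money formatting)."""

from __future__ import annotations

import math


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero (whole-dollar reporting convention).

    Internal arithmetic stays at full float precision; this is applied only
    when a number is displayed.
    """
    scale = 10.0**digits
    scaled = x * scale
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    out = rounded / scale
    return int(out) if digits <= 0 else out


def fmt_usd(x: float) -> str:
    """Whole-dollar display with thousands separators, e.g. ``$15,593``."""
    v = round_half_away(x)
    sign = "-" if v < 0 else ""
    return f"{sign}${abs(v):,}"
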