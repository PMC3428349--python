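"""Small shared numeric helpers."""

from __future__ import annotations

import decimal
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.05 at the cut always rounds away from zero)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def exact_fraction(threshold) -> Fraction:
    """Convert a threshold given as float/str/Fraction to an exact Fraction.

    Floats are interpreted through their shortest decimal repr, so 0.001
    becomes exactly 1/1000 — thresholds compare against exact count ratios,
    never against binary-float approximations.
    """
    if isinstance(threshold, Fraction):
        return threshold
    return Fraction(repr(threshold) if isinstance(threshold, float) else str(threshold))
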