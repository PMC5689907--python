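"""Half-up rounding helpers for report-convention comparisons.

Commissioning reports round half-up at a fixed decimal precision (or to
two significant figures for uncertainty tables); Python's built-in
``round`` is banker's rounding, so these helpers exist to reproduce the
report convention exactly.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round half-up to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)
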