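"""Small shared numerics: printed-table percentage rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Share of ``numerator`` in ``denominator`` as a percentage.

    Rounded half-up to ``decimals`` places, matching how printed descriptive
    tables round (so 19.25 -> 19.3, not banker's 19.2).  Zero denominator
    yields 0.0.
    """
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
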