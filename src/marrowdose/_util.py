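"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

MEV_TO_J = 1.602176634e-13


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed dose tables).

    Python's built-in ``round`` is banker's rounding; report columns here follow
    the half-away-from-zero convention instead, so 20.85 -> 20.9 and -0.5 -> -1.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
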