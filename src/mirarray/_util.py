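"""Small shared helpers: display rounding and percentage reporting."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do.

    Python's built-in ``round`` is banker's rounding; report tables in this
    field round 0.5 up, so 20.715 -> 20.72 at two digits.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """``part`` as a percentage of ``whole``, rounded half-up.

    Used for summary arithmetic such as "261 of 1260 probes -> 20.71%" or
    "14 of 72 mapped miRNAs -> 19.44%".
    """
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole, ndigits)
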