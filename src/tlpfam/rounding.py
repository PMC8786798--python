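"""Half-up decimal rounding, used wherever values are reported at a fixed
number of printed decimals (Python's built-in round() is banker's rounding,
which disagrees with the reporting convention on exact halves such as
0.125 -> 0.13)."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
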