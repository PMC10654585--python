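"""Half-up decimal rounding on exact ratios.

Published occurrence tables round percentages half-up (e.g. 81/144 ->
56.25 -> 56.3). Python's builtin ``round`` is half-even and binary floats
cannot represent most decimal ratios exactly, so percentages are computed
from the integer counts with :mod:`decimal` arithmetic.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction

__all__ = ["round_half_up", "pct"]


def round_half_up(x: float | int | Decimal | Fraction, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    elif isinstance(x, Decimal):
        d = x
    else:
        d = Decimal(repr(float(x)))
    with localcontext() as ctx:
        ctx.prec = 50
        q = Decimal(1).scaleb(-ndigits)
        return float(d.quantize(q, rounding=ROUND_HALF_UP))


def pct(numer: int, denom: int, ndigits: int = 1) -> float:
    """Exact percentage ``100 * numer / denom`` rounded half-up.

    Carried out entirely in decimal arithmetic so that e.g.
    ``pct(81, 144, 1) == 56.3`` and ``pct(87, 144, 2) == 60.42``.
    """
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    with localcontext() as ctx:
        ctx.prec = 50
        d = Decimal(numer) * 100 / Decimal(denom)
        q = Decimal(1).scaleb(-ndigits)
        return float(d.quantize(q, rounding=ROUND_HALF_UP))
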