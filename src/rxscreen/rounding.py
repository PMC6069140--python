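"""Significant-figure rounding in decimal arithmetic.

Regulatory screening tables are published at fixed significant figures, and
reproducing them requires rounding that is exact on decimal boundaries
(12.5/1000 = 0.0125 must round to 0.013 at two figures). Binary floats
cannot represent such boundaries, so all rounding here goes through
:mod:`decimal` with half-away-from-zero ties.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["to_decimal", "round_sig"]


def to_decimal(x) -> Decimal:
    """Convert via ``str`` so the decimal literal, not the binary float
    representation, is what gets rounded."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


def round_sig(x, n: int) -> Decimal:
    """Round positive ``x`` to ``n`` significant figures, ties away from zero."""
    if n < 1:
        raise ValueError("need at least one significant figure")
    d = to_decimal(x)
    if d <= 0:
        raise ValueError(f"round_sig requires a positive value, got {x}")
    quantum = Decimal(1).scaleb(d.adjusted() - n + 1)
    return d.quantize(quantum, rounding=ROUND_HALF_UP)
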