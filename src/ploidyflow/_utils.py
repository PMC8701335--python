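"""Small shared numerics used across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: conversion factor between picograms of DNA and megabase pairs
PG_TO_MBP = 978.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as in printed reports.

    Python's builtin ``round`` uses banker's rounding; reported genome sizes
    and indices follow the conventional half-up rule instead.  A 1e-9 nudge
    absorbs binary representation error of decimal inputs (e.g. a mean of
    3-decimal values landing at ...4999999...).
    """
    sign = -1.0 if x < 0 else 1.0
    shifted = Decimal(repr(abs(x) + 1e-9))
    q = shifted.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return sign * float(q)
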