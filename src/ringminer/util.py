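"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in input sequences: the 20 amino acids plus ambiguity X
SEQUENCE_ALPHABET = AA20 | {"X"}


def percent(count: float, total: float, ndigits: int = 2) -> float:
    """100*count/total with half-up rounding at ``ndigits`` decimals.

    Half-up (not banker's) rounding so reported percentages match the
    convention of hand-computed tables.
    """
    if total == 0:
        return 0.0
    value = Decimal(100) * Decimal(count) / Decimal(total)
    q = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
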