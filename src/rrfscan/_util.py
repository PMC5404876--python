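"""Small shared helpers: nucleotide arithmetic and report rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_bases(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report percentages are conventionally printed.

    Python's built-in round() uses banker's rounding, which would print 99.985 as 99.98
    or 99.99 depending on the binary representation; reports need the deterministic
    half-up convention.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded for reports."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)
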