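"""Small shared helpers: sequence manipulation and presentation rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed summary tables conventionally do.

    Python's built-in ``round`` is banker's rounding; percentage columns in
    sequencing summaries are half-up, so 0.125 -> 0.13 at two digits.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact ratio as a half-up rounded percentage (avoids float division bias)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def mean_phred(qual: str, offset: int = 33) -> float:
    """Mean Phred quality of a Phred+33 encoded quality string."""
    if not qual:
        return 0.0
    return sum(ord(c) - offset for c in qual) / len(qual)
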