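"""Shared low-level helpers: sequence canonicalization and rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def canonical(seq: str) -> str:
    """Uppercase and map U->T so RNA and DNA spellings compare equal."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return canonical(seq).translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in canonical(seq))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do.

    Python's round() is banker's rounding; frequency tables in the report
    layer round 2.455 -> 2.46, so we go through Decimal.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
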