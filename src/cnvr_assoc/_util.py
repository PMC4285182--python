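"""Small shared helpers: half-up rounding and chromosome ordering."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    Python's builtin ``round`` is banker's rounding; carrier percentages and
    kb lengths in the reported tables use half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr22 < chrX < chrY < chrM."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (int(body), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (special.get(body.upper(), 26), body)
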