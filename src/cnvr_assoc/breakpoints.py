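"""Breakpoint arithmetic and junction microhomology for tandem duplications.

In a head-to-tail tandem duplication the junction joins the sequence
ending at the distal breakpoint to the sequence beginning after the
proximal breakpoint; microhomology is the stretch of identical bases
shared by the two breakpoint-forming ends, i.e. the longest common suffix
of the two flanks read backwards from each breakpoint.
"""
from __future__ import annotations

from ._util import round_half_up

_VALID_BASES = frozenset("ACGTN")


def cnv_length(chrom: str, start: int, end: int) -> tuple[int, float]:
    """Length of a CNV from its 1-based inclusive breakpoint coordinates.

    Returns (length in bp, length in kb rounded half-up to one decimal).
    """
    if start > end:
        raise ValueError(f"{chrom}:{start}-{end}: start > end")
    length_bp = end - start + 1
    return length_bp, round_half_up(length_bp / 1000.0, 1)


def junction_microhomology(proximal_flank: str, distal_flank: str) -> int:
    """Microhomology length at a duplication junction.

    Both arguments are uppercase ACGTN sequences ending at their
    respective breakpoints; the result is the number of identical bases
    walking backwards from each breakpoint.  ``N`` never matches.
    """
    for name, seq in (("proximal_flank", proximal_flank), ("distal_flank", distal_flank)):
        if not seq:
            raise ValueError(f"{name} must be non-empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"{name} contains non-nucleotide characters {sorted(bad)}")
    n = 0
    for p, d in zip(reversed(proximal_flank), reversed(distal_flank)):
        if p != d or p == "N":
            break
        n += 1
    return n
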