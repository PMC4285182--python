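"""Per-sample two-caller consensus CNV calls.

A CNV is retained only when both calling algorithms report the same type
of event for the same individual at the same locus.  The consensus
interval is the *intersection* of the two callers' intervals — the
conservative reading of "called by both" — optionally gated by a
reciprocal-overlap threshold.  Overlapping consensus intervals of the same
type within one sample are merged afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import chrom_sort_key
from .io_formats import CnvCall, ValidationError


@dataclass(frozen=True)
class ConsensusCall:
    """A CNV interval supported by both callers for one sample.

    ``copy_number`` is the more extreme caller estimate toward the shared
    type (max for duplications, min for deletions), preserving multicopy
    information.  ``sources`` holds the contributing caller calls.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    copy_number: int | None = None
    sources: tuple[CnvCall, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("consensus interval has end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _extreme_cn(cnv_type: str, cns: Iterable[int | None]) -> int | None:
    values = [cn for cn in cns if cn is not None]
    if not values:
        return None
    return max(values) if cnv_type == "duplication" else min(values)


def intersect_caller_calls(
    calls: Sequence[CnvCall],
    min_reciprocal_overlap: float = 0.0,
) -> list[ConsensusCall]:
    """Intersect the two callers' calls per sample, chromosome and type.

    Every overlapping pair of intervals (one per caller) whose overlap is
    at least ``min_reciprocal_overlap`` of *both* interval lengths yields a
    candidate consensus interval equal to the pair's intersection; calls
    supported by a single caller are dropped; overlapping candidates of
    the same type within a sample are merged.  Exactly two caller ids may
    be present.
    """
    if not 0.0 <= min_reciprocal_overlap <= 1.0:
        raise ValueError("min_reciprocal_overlap must be in [0, 1]")
    caller_ids = sorted({c.caller_id for c in calls})
    if len(caller_ids) > 2:
        raise ValidationError(
            f"expected at most two caller ids, got {caller_ids}"
        )
    if len(caller_ids) < 2:
        return []
    first, second = caller_ids

    groups: dict[tuple[str, str, str], tuple[list[CnvCall], list[CnvCall]]] = {}
    for call in calls:
        key = (call.sample_id, call.chrom, call.cnv_type)
        pair = groups.setdefault(key, ([], []))
        pair[0 if call.caller_id == first else 1].append(call)

    out: list[ConsensusCall] = []
    for (sample_id, chrom, cnv_type), (calls_a, calls_b) in groups.items():
        candidates: list[tuple[int, int, tuple[CnvCall, CnvCall]]] = []
        for a in calls_a:
            for b in calls_b:
                lo, hi = max(a.start, b.start), min(a.end, b.end)
                overlap = hi - lo + 1
                if overlap < 1:
                    continue
                if min_reciprocal_overlap > 0.0 and (
                    overlap < min_reciprocal_overlap * a.length
                    or overlap < min_reciprocal_overlap * b.length
                ):
                    continue
                candidates.append((lo, hi, (a, b)))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        merged_start, merged_end, sources = (
            candidates[0][0],
            candidates[0][1],
            list(candidates[0][2]),
        )
        merged: list[ConsensusCall] = []

        def _emit(start: int, end: int, srcs: list[CnvCall]) -> None:
            uniq = tuple(dict.fromkeys(srcs))
            merged.append(
                ConsensusCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cnv_type=cnv_type,
                    copy_number=_extreme_cn(cnv_type, (s.copy_number for s in uniq)),
                    sources=uniq,
                )
            )

        for lo, hi, pair in candidates[1:]:
            if lo <= merged_end:  # >=1 shared base with the growing interval
                merged_end = max(merged_end, hi)
                sources.extend(pair)
            else:
                _emit(merged_start, merged_end, sources)
                merged_start, merged_end, sources = lo, hi, list(pair)
        _emit(merged_start, merged_end, sources)
        out.extend(merged)

    out.sort(key=lambda c: (c.sample_id, chrom_sort_key(c.chrom), c.start, c.cnv_type))
    return out
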