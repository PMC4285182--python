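"""Per-individual genomic CNV burden, outlier flagging, length comparison.

Genomic burden is the cumulative length (bp) of all consensus CNVs carried
by one individual.  Outliers are individuals whose total burden exceeds a
fold multiple of the median burden of *the rest* of their study group
(leave-one-out median), mirroring how extreme carriers are singled out in
case-control CNV screens.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .consensus import ConsensusCall
from .io_formats import Sample, ValidationError


@dataclass(frozen=True)
class BurdenSummary:
    sample_id: str
    n_cnvs: int
    n_del: int
    n_dup: int
    total_del_bp: int
    total_dup_bp: int
    total_bp: int
    outlier: bool = False


def compute_burden(
    consensus: Sequence[ConsensusCall],
    samples: Sequence[Sample],
) -> list[BurdenSummary]:
    """Cumulative deletion/duplication lengths per individual.

    Lengths are summed as end - start + 1.  Samples with zero calls are
    included with zero totals.  Overlapping same-type calls within one
    sample are rejected: they must have been merged upstream, otherwise
    totals would double-count bases.
    """
    per_sample: dict[str, list[ConsensusCall]] = {s.sample_id: [] for s in samples}
    for call in consensus:
        if call.sample_id not in per_sample:
            raise KeyError(f"call sample {call.sample_id!r} not in sample sheet")
        per_sample[call.sample_id].append(call)

    out = []
    for sample in samples:
        calls = sorted(
            per_sample[sample.sample_id],
            key=lambda c: (c.cnv_type, c.chrom, c.start),
        )
        for prev, cur in zip(calls, calls[1:]):
            if (
                prev.cnv_type == cur.cnv_type
                and prev.chrom == cur.chrom
                and cur.start <= prev.end
            ):
                raise ValidationError(
                    f"sample {sample.sample_id}: overlapping {cur.cnv_type} calls "
                    f"{prev.chrom}:{prev.start}-{prev.end} and "
                    f"{cur.chrom}:{cur.start}-{cur.end} (merge upstream)"
                )
        n_del = sum(1 for c in calls if c.cnv_type == "deletion")
        n_dup = len(calls) - n_del
        del_bp = sum(c.length for c in calls if c.cnv_type == "deletion")
        dup_bp = sum(c.length for c in calls if c.cnv_type == "duplication")
        out.append(
            BurdenSummary(
                sample_id=sample.sample_id,
                n_cnvs=len(calls),
                n_del=n_del,
                n_dup=n_dup,
                total_del_bp=del_bp,
                total_dup_bp=dup_bp,
                total_bp=del_bp + dup_bp,
            )
        )
    return out


def flag_outliers(
    burdens: Sequence[BurdenSummary],
    sample_ids: Sequence[str] | None = None,
    fold: float = 5.0,
) -> list[BurdenSummary]:
    """Flag individuals whose burden exceeds ``fold`` times the rest's median.

    ``sample_ids`` selects the comparison group (e.g. the RM cases); by
    default all summaries form one group.  For each member the median is
    recomputed over the other members (leave-one-out).  Returns a new list
    with flags set; samples outside the group keep ``outlier=False``.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    group = set(sample_ids) if sample_ids is not None else {b.sample_id for b in burdens}
    members = [b for b in burdens if b.sample_id in group]
    if len(members) < 2:
        raise ValueError("outlier flagging needs a group of at least 2 samples")
    totals = {b.sample_id: b.total_bp for b in members}
    out = []
    for b in burdens:
        if b.sample_id in group:
            others = [t for sid, t in totals.items() if sid != b.sample_id]
            flagged = b.total_bp > fold * float(np.median(others))
            out.append(replace(b, outlier=flagged))
        else:
            out.append(replace(b, outlier=False))
    return out


def _mann_whitney_exact(lengths_a: np.ndarray, lengths_b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating group assignments.

    Enumerates all C(n_a + n_b, n_a) ways to assign the pooled values to
    the first group; handles ties naturally because U is computed from
    midranks of the fixed pooled multiset.  Two-sided P is the probability
    of a U at least as far from the null mean as observed.
    """
    n_a, n_b = len(lengths_a), len(lengths_b)
    pooled = np.concatenate([lengths_a, lengths_b])
    ranks = rankdata(pooled)
    correction = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - correction)
    mu = n_a * n_b / 2.0
    stats = [
        sum(ranks[i] for i in combo) - correction
        for combo in itertools.combinations(range(n_a + n_b), n_a)
    ]
    dev = abs(u_obs - mu) - 1e-9
    p = sum(1 for u in stats if abs(u - mu) >= dev) / len(stats)
    return u_obs, min(1.0, p)


def compare_length_distributions(
    lengths_a: Sequence[float],
    lengths_b: Sequence[float],
) -> tuple[float, float]:
    """Mann-Whitney U comparison of two length distributions.

    Returns (U of the first sample, two-sided P).  Uses exact enumeration
    when both samples have at most 8 observations; otherwise the normal
    approximation with midrank ties, tie-corrected variance, and a 0.5
    continuity correction.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size <= 8 and b.size <= 8:
        return _mann_whitney_exact(a, b)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = rankdata(np.concatenate([a, b]))
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return u, 1.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    return u, min(1.0, 2.0 * float(norm.sf(z)))
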