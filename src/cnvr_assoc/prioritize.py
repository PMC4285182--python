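"""Three-criterion CNVR prioritization cascade.

Regions are carried forward for experimental confirmation when they are
(1) recurrent — carried by more than one individual; (2) case-enriched —
found only among cases, or over-represented in cases with a carrier odds
ratio at or above a threshold; and (3) near a biological candidate gene —
overlapping a user-supplied candidate interval extended by a proximity
window (~200 kb by default).  The candidate-gene list encodes literature
judgment and is supplied by the user, not computed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cnvr import CnvRegion, cnvr_carrier_table
from .io_formats import GeneAnnotation, Sample, group_sizes

STAGES = ("recurrent", "case_enriched", "candidate_proximity")


@dataclass(frozen=True)
class PrioritizationReport:
    stage_survivors: dict[str, list[str]]
    stage_counts: dict[str, int]
    parameters: dict

    def survivors(self) -> list[str]:
        """Regions surviving the full cascade."""
        return list(self.stage_survivors[STAGES[-1]])


def _carrier_or(a: int, n_cases: int, c: int, n_controls: int) -> float:
    """Cross-product carrier odds ratio for one region.

    Haldane-Anscombe +0.5 on every cell is applied only when exactly one
    cell is zero and the region has carriers in both groups; a table with
    two zero cells (everyone or no one a carrier in both groups) carries
    no enrichment signal and returns 1.0.
    """
    b, d = n_cases - a, n_controls - c
    cells = [a, b, c, d]
    n_zero = sum(1 for x in cells if x == 0)
    if n_zero == 1 and a > 0 and c > 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    elif n_zero == 0:
        a_, b_, c_, d_ = (float(x) for x in cells)
    else:
        return 1.0
    return (a_ * d_) / (b_ * c_)


def prioritize_cnvrs(
    cnvrs: Sequence[CnvRegion],
    samples: Sequence[Sample],
    candidate_genes: Sequence[GeneAnnotation],
    min_carriers: int = 2,
    min_or: float = 1.5,
    proximity_bp: int = 200_000,
) -> PrioritizationReport:
    """Apply the recurrence / case-enrichment / candidate-proximity cascade.

    Stage 2 keeps regions with at least one case carrier and zero control
    carriers, or with carrier OR >= ``min_or`` (cases vs fertile controls,
    denominators from the sample sheet).  Stage 3 keeps regions
    overlapping a candidate gene interval extended by ``proximity_bp`` on
    either side.
    """
    if min_or < 1.0:
        raise ValueError("min_or must be >= 1")
    if min_carriers < 0 or proximity_bp < 0:
        raise ValueError("min_carriers and proximity_bp must be >= 0")

    if any(r.carrier_counts is None for r in cnvrs):
        cnvr_carrier_table(cnvrs, samples)
    sizes = group_sizes(samples)
    n_cases = sizes.get("case", 0)
    n_controls = sizes.get("fertile_control", 0)

    stage1 = [r for r in cnvrs if r.n_carriers >= min_carriers]

    stage2 = []
    for r in stage1:
        a = r.carrier_counts.get("case", 0)
        c = r.carrier_counts.get("fertile_control", 0)
        if a >= 1 and c == 0:
            stage2.append(r)
        elif _carrier_or(a, n_cases, c, n_controls) >= min_or:
            stage2.append(r)

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in candidate_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    stage3 = [
        r
        for r in stage2
        if any(
            g.start - proximity_bp <= r.end and g.end + proximity_bp >= r.start
            for g in by_chrom.get(r.chrom, ())
        )
    ]

    survivors = {
        "recurrent": [r.cnvr_id for r in stage1],
        "case_enriched": [r.cnvr_id for r in stage2],
        "candidate_proximity": [r.cnvr_id for r in stage3],
    }
    return PrioritizationReport(
        stage_survivors=survivors,
        stage_counts={k: len(v) for k, v in survivors.items()},
        parameters={
            "min_carriers": min_carriers,
            "min_or": min_or,
            "proximity_bp": proximity_bp,
            "candidate_genes": [g.gene_id for g in candidate_genes],
        },
    )
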