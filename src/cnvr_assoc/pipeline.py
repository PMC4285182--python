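"""End-to-end orchestration: synthetic cohort -> calls -> CNVRs -> association.

Convenience wrappers that chain the pipeline stages in their natural
order, used for parameter-recovery experiments and as a worked example of
the library API.
"""
from __future__ import annotations

from dataclasses import replace

from .assoc import AssociationResult, ContingencyTable, association_2x2
from .cnvr import CnvRegion, build_cnvrs, cnvr_carrier_table
from .consensus import intersect_caller_calls
from .io_formats import group_sizes
from .synthetic_data import (
    SimulationConfig,
    simulate_caller_observations,
    simulate_cohort,
)


def risk_locus_association(
    config: SimulationConfig,
    zero_cell_policy: str = "haldane",
) -> tuple[AssociationResult, CnvRegion]:
    """Simulate a cohort and recover the carrier association at the risk locus.

    Runs the full chain — cohort simulation, two-caller observation,
    consensus intersection, CNVR construction, carrier counting — then
    tests case vs fertile-control carriership of the CNVR overlapping the
    configured risk locus.  The Haldane zero-cell policy is the default
    because small control groups can legitimately contain zero carriers.
    """
    samples, profiles = simulate_cohort(config)
    calls = simulate_caller_observations(profiles, config)
    consensus = intersect_caller_calls(calls)
    regions = build_cnvrs(consensus)
    cnvr_carrier_table(regions, samples)

    locus = config.risk_cnvr
    overlapping = [
        r
        for r in regions
        if r.chrom == locus.chrom and r.start <= locus.end and r.end >= locus.start
    ]
    if not overlapping:
        raise RuntimeError("no CNVR recovered at the risk locus")
    region = max(
        overlapping,
        key=lambda r: min(r.end, locus.end) - max(r.start, locus.start),
    )
    sizes = group_sizes(samples)
    table = ContingencyTable.from_carriers(
        sizes.get("case", 0),
        region.carrier_counts.get("case", 0),
        sizes.get("fertile_control", 0),
        region.carrier_counts.get("fertile_control", 0),
    )
    result = association_2x2(
        table, zero_cell_policy=zero_cell_policy, stratum_label="synthetic"
    )
    return result, region


def coverage_of_true_or(
    base_config: SimulationConfig,
    n_replicates: int,
    seed: int,
) -> float:
    """Fraction of seeded replicates whose 95% CI covers the generative OR."""
    locus = base_config.risk_cnvr
    p1, p0 = locus.carrier_freq_cases, locus.carrier_freq_controls
    true_or = (p1 / (1 - p1)) / (p0 / (1 - p0))
    covered = 0
    for rep in range(n_replicates):
        config = replace(base_config, seed=(seed + 977 * rep) % 2**31)
        result, _ = risk_locus_association(config)
        covered += result.ci_low <= true_or <= result.ci_high
    return covered / n_replicates
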