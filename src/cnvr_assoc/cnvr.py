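"""Discrete CNV regions (CNVRs): cross-sample merging, carrier counts, genes.

A CNVR is the transitive closure of interval overlap of consensus calls
across *all* individuals: any two calls sharing at least one base belong
to the same region, and the region's span is the union of its members.
Deletions and duplications at the same locus merge into one CNVR whose
``type_composition`` records the mix; use ``split_by_type=True`` for
per-type regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._util import chrom_sort_key
from .consensus import ConsensusCall
from .io_formats import GeneAnnotation, Sample, group_sizes

CASE_SUBTYPES = ("primary_rm", "secondary_rm")


@dataclass
class CnvRegion:
    """One discrete CNV region with its member calls and carriers.

    ``carriers`` / ``carrier_counts`` (per study group) are filled in by
    :func:`cnvr_carrier_table` once a sample sheet is available.
    """

    cnvr_id: str
    chrom: str
    start: int
    end: int
    type_composition: str  # deletion_only | duplication_only | mixed
    member_calls: tuple[ConsensusCall, ...]
    carrier_sample_ids: tuple[str, ...]
    carriers: dict[str, list[str]] | None = None
    carrier_counts: dict[str, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_sample_ids)


def _composition(types: set[str]) -> str:
    if types == {"deletion"}:
        return "deletion_only"
    if types == {"duplication"}:
        return "duplication_only"
    return "mixed"


def build_cnvrs(
    consensus: Sequence[ConsensusCall],
    split_by_type: bool = False,
) -> list[CnvRegion]:
    """Merge overlapping consensus calls across all individuals into CNVRs.

    Returns mutually non-overlapping regions sorted by chromosome and
    start; every consensus base lies in exactly one region.
    """
    def _key(call: ConsensusCall):
        type_part = call.cnv_type if split_by_type else ""
        return (type_part, chrom_sort_key(call.chrom), call.start, call.end)

    ordered = sorted(consensus, key=_key)
    clusters: list[list[ConsensusCall]] = []
    for call in ordered:
        if clusters:
            last = clusters[-1]
            same_track = last[0].chrom == call.chrom and (
                not split_by_type or last[0].cnv_type == call.cnv_type
            )
            if same_track and call.start <= max(c.end for c in last):
                last.append(call)
                continue
        clusters.append([call])

    clusters.sort(key=lambda cl: (chrom_sort_key(cl[0].chrom), min(c.start for c in cl)))
    regions: list[CnvRegion] = []
    for idx, members in enumerate(clusters, start=1):
        regions.append(
            CnvRegion(
                cnvr_id=f"CNVR{idx:04d}",
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                type_composition=_composition({c.cnv_type for c in members}),
                member_calls=tuple(members),
                carrier_sample_ids=tuple(
                    sorted({c.sample_id for c in members})
                ),
            )
        )
    return regions


def cnvr_carrier_table(
    cnvrs: Sequence[CnvRegion],
    samples: Sequence[Sample],
) -> pd.DataFrame:
    """Carrier counts per CNVR by study group and, for cases, by RM subtype.

    Denominators (``n_samples``) are recruitment counts from the sample
    sheet, not observed-carrier counts.  Also fills each region's
    ``carriers`` / ``carrier_counts`` in place.  A carrier sample id that
    is absent from the sheet is an error.
    """
    by_id = {s.sample_id: s for s in samples}
    sizes = group_sizes(samples)
    subtype_sizes = {
        st: sum(1 for s in samples if s.group == "case" and s.subtype == st)
        for st in CASE_SUBTYPES
    }
    rows = []
    for region in cnvrs:
        carriers: dict[str, list[str]] = {g: [] for g in sizes}
        for sid in region.carrier_sample_ids:
            sample = by_id.get(sid)
            if sample is None:
                raise KeyError(
                    f"carrier {sid!r} of {region.cnvr_id} is not in the sample sheet"
                )
            carriers[sample.group].append(sid)
        region.carriers = carriers
        region.carrier_counts = {g: len(v) for g, v in carriers.items()}
        for group in sorted(sizes):
            rows.append(
                (region.cnvr_id, group, "all", len(carriers[group]), sizes[group])
            )
            if group == "case":
                for st in CASE_SUBTYPES:
                    n = sum(1 for sid in carriers[group] if by_id[sid].subtype == st)
                    rows.append((region.cnvr_id, group, st, n, subtype_sizes[st]))
    return pd.DataFrame(
        rows, columns=["cnvr_id", "group", "subtype", "n_carriers", "n_samples"]
    )


def genes_in_cnvrs(
    cnvrs: Sequence[CnvRegion],
    genes: Sequence[GeneAnnotation],
    flank_bp: int = 10_000,
    samples: Sequence[Sample] | None = None,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Genes overlapping each CNVR extended by ``flank_bp`` on either side.

    A gene is reported for a region when its interval overlaps
    [start - flank, end + flank] by at least one base.  Returns the
    per-CNVR mapping and, when a sample sheet is given, the pooled unique
    gene list per study group (genes of every region carried by at least
    one member of the group).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    per_cnvr: dict[str, list[str]] = {}
    for region in cnvrs:
        lo, hi = region.start - flank_bp, region.end + flank_bp
        hits = sorted(
            {
                g.gene_id
                for g in by_chrom.get(region.chrom, ())
                if g.start <= hi and g.end >= lo
            }
        )
        per_cnvr[region.cnvr_id] = hits

    per_group: dict[str, list[str]] = {}
    if samples is not None:
        group_of = {s.sample_id: s.group for s in samples}
        pools: dict[str, set[str]] = {}
        for region in cnvrs:
            groups_hit = {
                group_of[sid]
                for sid in region.carrier_sample_ids
                if sid in group_of
            }
            for grp in groups_hit:
                pools.setdefault(grp, set()).update(per_cnvr[region.cnvr_id])
        per_group = {grp: sorted(v) for grp, v in pools.items()}
    return per_cnvr, per_group


def cnvrs_to_bed(cnvrs: Sequence[CnvRegion], path) -> None:
    """Export CNVRs as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cnvr_id}\t"
                f"{r.n_carriers}\t.\n"
            )
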