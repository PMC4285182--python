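import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvr_assoc import (
    ConsensusCall,
    GeneAnnotation,
    Sample,
    build_cnvrs,
    cnvr_carrier_table,
    genes_in_cnvrs,
    intersect_caller_calls,
)

from conftest import random_calls


def _cc(sample, start, end, cnv_type="duplication", chrom="chr1"):
    return ConsensusCall(sample, chrom, start, end, cnv_type)


def cnvr_span_oracle(calls):
    """Connected components of interval overlap, computed on base sets."""
    items = [(c.chrom, set(range(c.start, c.end + 1))) for c in calls]
    components = []
    for chrom, bases in items:
        merged = bases
        keep = []
        for comp_chrom, comp in components:
            if comp_chrom == chrom and comp & merged:
                merged |= comp
            else:
                keep.append((comp_chrom, comp))
        components = keep + [(chrom, merged)]
    return sorted((chrom, min(b), max(b)) for chrom, b in components)


class TestBuildCnvrs:
    def test_single_call_single_region(self):
        (r,) = build_cnvrs([_cc("S1", 100, 200)])
        assert (r.start, r.end, r.carrier_sample_ids) == (100, 200, ("S1",))
        assert r.type_composition == "duplication_only"

    def test_transitive_overlap_chains_into_one_region(self):
        calls = [_cc("S1", 100, 200), _cc("S2", 150, 300), _cc("S3", 250, 400)]
        (r,) = build_cnvrs(calls)
        assert (r.start, r.end) == (100, 400)
        assert r.carrier_sample_ids == ("S1", "S2", "S3")
        assert [(r.chrom, r.start, r.end)] == cnvr_span_oracle(calls)

    def test_disjoint_calls_give_separate_regions(self):
        regions = build_cnvrs([_cc("S1", 100, 200), _cc("S2", 300, 400)])
        assert [(r.start, r.end) for r in regions] == [(100, 200), (300, 400)]

    def test_mixed_types_merge_into_one_region_by_default(self):
        calls = [_cc("S1", 100, 200, "deletion"), _cc("S2", 150, 250, "duplication")]
        (r,) = build_cnvrs(calls)
        assert r.type_composition == "mixed"

    def test_split_by_type_keeps_types_separate(self):
        calls = [_cc("S1", 100, 200, "deletion"), _cc("S2", 150, 250, "duplication")]
        regions = build_cnvrs(calls, split_by_type=True)
        assert len(regions) == 2
        assert {r.type_composition for r in regions} == {
            "deletion_only",
            "duplication_only",
        }

    @given(st.integers(0, 2**32 - 1), st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_spans_equal_connected_component_oracle(self, seed, n_calls):
        rng = np.random.default_rng(seed)
        calls = [
            _cc(
                f"S{int(rng.integers(1, 5))}",
                s := int(rng.integers(1, 2000)),
                s + int(rng.integers(0, 150)),
                chrom=f"chr{int(rng.integers(1, 3))}",
            )
            for _ in range(n_calls)
        ]
        regions = build_cnvrs(calls)
        assert [(r.chrom, r.start, r.end) for r in regions] == sorted(
            cnvr_span_oracle(calls), key=lambda t: (int(t[0][3:]), t[1])
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_partition_no_two_regions_overlap_and_bases_covered(self, seed):
        rng = np.random.default_rng(seed)
        calls = [
            _cc(
                f"S{int(rng.integers(1, 4))}",
                s := int(rng.integers(1, 1500)),
                s + int(rng.integers(0, 120)),
            )
            for _ in range(25)
        ]
        regions = build_cnvrs(calls)
        for r1, r2 in zip(regions, regions[1:]):
            if r1.chrom == r2.chrom:
                assert r1.end < r2.start
        for call in calls:
            containing = [
                r
                for r in regions
                if r.chrom == call.chrom and r.start <= call.start and call.end <= r.end
            ]
            assert len(containing) == 1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_rebuilding_from_region_spans_is_a_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        calls = [
            _cc(
                f"S{int(rng.integers(1, 4))}",
                s := int(rng.integers(1, 1500)),
                s + int(rng.integers(0, 120)),
            )
            for _ in range(20)
        ]
        regions = build_cnvrs(calls)
        again = build_cnvrs([_cc("POOL", r.start, r.end, chrom=r.chrom) for r in regions])
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (r.chrom, r.start, r.end) for r in regions
        ]


class TestCarrierTable:
    def _sheet(self, n_cases=80, n_controls=90):
        cases = [
            Sample(
                f"RM{i}",
                "female",
                "case",
                "primary_rm" if i < n_cases // 2 else "secondary_rm",
                "EE",
            )
            for i in range(n_cases)
        ]
        controls = [
            Sample(f"FC{i}", "female", "fertile_control", "none", "EE")
            for i in range(n_controls)
        ]
        return cases + controls

    def test_counts_match_reported_carrier_table_shape(self):
        # 6 case carriers of 80 cases vs 1 control carrier of 90 controls
        samples = self._sheet()
        calls = [_cc(f"RM{i}", 100, 200) for i in range(6)] + [_cc("FC0", 120, 180)]
        regions = build_cnvrs(calls)
        table = cnvr_carrier_table(regions, samples)
        case_row = table[(table.group == "case") & (table.subtype == "all")].iloc[0]
        ctrl_row = table[table.group == "fertile_control"].iloc[0]
        assert (case_row.n_carriers, case_row.n_samples) == (6, 80)
        assert (ctrl_row.n_carriers, ctrl_row.n_samples) == (1, 90)

    def test_case_counts_partitioned_by_subtype(self):
        samples = self._sheet(n_cases=10, n_controls=5)
        calls = [_cc("RM0", 100, 200), _cc("RM1", 100, 200), _cc("RM9", 100, 200)]
        table = cnvr_carrier_table(build_cnvrs(calls), samples)
        primary = table[table.subtype == "primary_rm"].iloc[0]
        secondary = table[table.subtype == "secondary_rm"].iloc[0]
        assert (primary.n_carriers, primary.n_samples) == (2, 5)
        assert (secondary.n_carriers, secondary.n_samples) == (1, 5)

    def test_no_carrier_region_reports_zero_rows_per_group(self):
        samples = self._sheet(n_cases=4, n_controls=4)
        regions = build_cnvrs([_cc("RM0", 100, 200)])
        # remove the only carrier's membership by pointing at a fresh sheet
        table = cnvr_carrier_table(regions, samples)
        ctrl = table[(table.group == "fertile_control")]
        assert (ctrl.n_carriers == 0).all()

    def test_all_samples_carriers_gives_full_counts(self):
        samples = self._sheet(n_cases=3, n_controls=2)
        calls = [_cc(s.sample_id, 100, 200) for s in samples]
        table = cnvr_carrier_table(build_cnvrs(calls), samples)
        all_rows = table[table.subtype == "all"]
        assert (all_rows.n_carriers == all_rows.n_samples).all()

    def test_unknown_carrier_rejected(self):
        samples = self._sheet(n_cases=2, n_controls=2)
        regions = build_cnvrs([_cc("GHOST", 100, 200)])
        with pytest.raises(KeyError, match="GHOST"):
            cnvr_carrier_table(regions, samples)

    def test_noiseless_synthetic_risk_region_matches_truth(self, small_cohort):
        config, samples, profiles, calls = small_cohort
        consensus = intersect_caller_calls(calls)
        regions = build_cnvrs(consensus)
        cnvr_carrier_table(regions, samples)
        locus = config.risk_cnvr
        (risk,) = [
            r
            for r in regions
            if r.chrom == locus.chrom and r.start <= locus.end and r.end >= locus.start
        ]
        truth = {
            p.sample_id for p in profiles if p.risk_copy_number(locus) > 2
        }
        assert set(risk.carrier_sample_ids) == truth


class TestGenesInCnvrs:
    def test_gene_within_flank_included(self):
        regions = build_cnvrs([_cc("S1", 2500, 3000)])
        genes = [GeneAnnotation("G1", "chr1", 1000, 2000)]
        per_cnvr, _ = genes_in_cnvrs(regions, genes, flank_bp=10_000)
        assert per_cnvr[regions[0].cnvr_id] == ["G1"]

    def test_gene_beyond_flank_excluded(self):
        regions = build_cnvrs([_cc("S1", 20_000, 30_000)])
        genes = [GeneAnnotation("G1", "chr1", 1000, 2000)]
        per_cnvr, _ = genes_in_cnvrs(regions, genes, flank_bp=10_000)
        assert per_cnvr[regions[0].cnvr_id] == []

    def test_negative_flank_rejected(self):
        regions = build_cnvrs([_cc("S1", 100, 200)])
        with pytest.raises(ValueError):
            genes_in_cnvrs(regions, [], flank_bp=-1)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_all_pairs_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = [
            _cc(
                f"S{i}",
                s := int(rng.integers(1, 50_000)),
                s + int(rng.integers(0, 5000)),
                chrom=f"chr{int(rng.integers(1, 3))}",
            )
            for i in range(20)
        ]
        genes = [
            GeneAnnotation(
                f"G{i}",
                f"chr{int(rng.integers(1, 3))}",
                s := int(rng.integers(1, 50_000)),
                s + int(rng.integers(0, 3000)),
            )
            for i in range(100)
        ]
        regions = build_cnvrs(calls)
        flank = 10_000
        per_cnvr, _ = genes_in_cnvrs(regions, genes, flank_bp=flank)
        for r in regions:
            expected = sorted(
                {
                    g.gene_id
                    for g in genes
                    if g.chrom == r.chrom
                    and g.start <= r.end + flank
                    and g.end >= r.start - flank
                }
            )
            assert per_cnvr[r.cnvr_id] == expected

    def test_pooled_gene_lists_per_group(self):
        samples = [
            Sample("RM1", "female", "case", "none", "EE"),
            Sample("FC1", "female", "fertile_control", "none", "EE"),
        ]
        calls = [_cc("RM1", 100, 200), _cc("FC1", 10_000_000, 10_000_100)]
        regions = build_cnvrs(calls)
        cnvr_carrier_table(regions, samples)
        genes = [
            GeneAnnotation("NEAR_CASE", "chr1", 150, 180),
            GeneAnnotation("NEAR_CTRL", "chr1", 10_000_050, 10_000_060),
        ]
        _, per_group = genes_in_cnvrs(regions, genes, flank_bp=0, samples=samples)
        assert per_group == {
            "case": ["NEAR_CASE"],
            "fertile_control": ["NEAR_CTRL"],
        }
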