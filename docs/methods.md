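# Methods

This note documents the models, conventions and design choices behind
`cnvr-assoc`, in the order the pipeline runs.

## Coordinates and formats

All internal coordinates are 1-based and inclusive on both ends, so an
interval [s, e] spans e − s + 1 bases; this matches how CNV breakpoints
are reported in the genetics literature (chr5:32,106,204–32,167,777 is a
61,574 bp = 61.6 kb event). BED input and output converts to and from
BED's 0-based half-open convention at the I/O boundary only; GFF3 is
already 1-based inclusive. Chromosome names are normalized to `chrN` on
input because CNV-call files mix dialects. A call with copy number 2 is
rejected rather than silently dropped: a "variant" record describing the
reference state is always an upstream error worth surfacing.

## Two-caller consensus

SNP-array CNV calling is noisy enough that production screens keep only
events reported by two independent algorithms (e.g. an Objective-Bayes
HMM and a generalized-genotyping HMM) for the same individual at the same
locus. "Same locus" is not a precise notion, so the implementation makes
the conservative choice: a consensus call is the *intersection* of an
overlapping pair of intervals, one per caller, same sample, same event
type; a configurable reciprocal-overlap threshold (default 0, i.e. any
overlap) can tighten the pairing. Overlapping consensus intervals of the
same type within one sample are merged afterwards, which makes the
consensus base set exactly {bases covered by both callers with the same
type} at threshold 0 — the property the brute-force per-base oracle in
the test suite checks. Deletions never form consensus with duplications:
type-discordant overlap is caller disagreement, not support. The copy
number of a consensus call is the more extreme caller estimate toward the
shared type (max for duplications, min for deletions) so that multicopy
loci keep their amplification signal.

## CNV regions (CNVRs)

CNVRs are the transitive closure of interval overlap across *all*
individuals: any chain of pairwise-overlapping consensus calls collapses
into one region spanning the union of its members. Regions are therefore
mutually non-overlapping, and rebuilding regions from their own spans is
a fixed point. Deletions and duplications merge into one region by
default (`type_composition` records the mix) because region counting in
CNV screens pools both; `split_by_type=True` gives per-type regions. A
carrier is any sample contributing at least one base of consensus overlap
— no fractional-overlap threshold. Denominators in carrier tables are
recruitment counts from the sample sheet, not observed-carrier counts,
since reported prevalence tables use recruitment denominators.

Gene lists per region take every annotated gene overlapping the region
extended by 10 kb on either side (the convention for preparing functional
enrichment inputs); enrichment testing itself is out of scope because it
depends on a live annotation database.

## Genomic burden

Burden is the cumulative length of all consensus CNVs per individual,
split by type. Overlapping same-type calls within one sample are rejected
(they must be merged upstream) because they would double-count bases.
Outlier flagging uses a leave-one-out median: a sample is an outlier when
its total exceeds `fold` (default 5) times the median burden of the
*other* members of its study group. The leave-one-out form matches the
idea of "exceeding the rest of the group" and keeps the reference median
robust when the group is small; it also makes flagging scale-equivariant.

Length distributions (duplications vs deletions) are compared with a
Mann–Whitney U test: exact enumeration of all C(n_a+n_b, n_a) group
assignments when both samples have ≤ 8 observations (midranks make this
valid under ties; two-sided P is the probability of a U at least as far
from n_a·n_b/2 as observed), otherwise a normal approximation with
midranks, tie-corrected variance and a 0.5 continuity correction. The
exact cutoff at 8 keeps the enumeration below C(16,8) = 12,870 states.

## CNVR prioritization

Three criteria applied as a cascade, each stage a subset of the previous:
(1) recurrence — total carriers ≥ 2; (2) case enrichment — zero control
carriers with ≥ 1 case carrier, or a carrier odds ratio ≥ 1.5 computed
from the cross-product of carrier counts against sample-sheet group
sizes; (3) candidate proximity — overlap with a user-supplied candidate
gene interval extended by 200 kb (configurable; the criterion encodes
literature judgment, which is not computable, so the gene list is an
input). In stage 2 the Haldane–Anscombe +0.5 correction is applied only
when exactly one cell of the 2×2 is zero and the region has carriers in
both groups; a table with two zero cells carries no enrichment signal and
is treated as null (OR 1).

## qPCR copy-number assignment

Normalized TaqMan ratios concentrate near m/2 for diploid copy number m.
Per sample, ratios of the assays inside the rearranged region are
averaged and doubled to a naive copy estimate. Classes are then assigned
by 1-D k-means with centroids initialized at the theoretical ratios 1.0,
1.5, 2.0, 2.5 (classes 2, 3, 4, >4). Only initial centroids that are
nearest to at least one sample are retained, fixing k deterministically —
published qPCR clusterings rarely report k or seeds, and the
deterministic scheme makes assignments reproducible and order-invariant.
Final clusters are labelled by the theoretical ratio closest to their
centroid, which stays correct even when the occupied classes are not
contiguous (e.g. only 2 and 4 copies present). Because the retained-k
rule guarantees k ≤ n, the nearest-ratio fallback for n < k is a
defensive guard only. TaqMan chemistry cannot resolve more than four
copies reliably, so any sample with naive estimate > 4.5 copies is forced
into the ">4" class regardless of cluster. A carrier is any sample with
≥ 3 diploid copies. At ratio noise sd ≤ 0.1 the 2-vs-3-copy boundary sits
≈ 3.5 sd from both centroids, which is what makes ≥ 99% class accuracy
achievable; the test suite measures this on generated panels.

## Carrier association and meta-analysis

Each stratum is a 2×2 carrier table. Inference is Wald on the log odds
ratio: beta = ln(ad/bc), se = √(1/a+1/b+1/c+1/d), 95% CI =
exp(beta ± 1.959964·se), two-sided normal P. This is numerically
identical (to ~10⁻⁶, verified against an expanded-data maximum-likelihood
logistic fit) to logistic regression of case status on carrier status,
and it reproduces published carrier-association tables by direct
arithmetic. The default zero-cell policy is to raise an error; the
Haldane +0.5-per-cell policy must be requested explicitly so that a
continuity correction is never applied silently.

Two fixed-effects combinations are provided. Inverse-variance: combined
beta = Σ(beta_i/se_i²)/Σ(1/se_i²), se = (Σ1/se_i²)^(−1/2). Weighted-z
(the METAL convention): z = Σ w_i z_i / √(Σ w_i²) with w_i = √n_eff,i and
n_eff = 4/(1/n_cases + 1/n_controls), which down-weights strata with
asymmetric case/control ratios. The n_eff convention was confirmed by
hand recomputation of published weighted-z P-values from their count
tables — the alternative n_eff = n_total does not reproduce them — and
both conventions are exposed (`effective_sample_size(...,
convention=...)`). Stratum z-values are taken directly as beta_i/se_i
rather than re-derived from rounded printed P-values, avoiding double
rounding. No heterogeneity statistics are computed (fixed-effects only).

## Breakpoint arithmetic and microhomology

CNV length from breakpoint coordinates is end − start + 1 (kb values
rounded half-up to one decimal, the convention of printed tables — note
`round_half_up` throughout, since Python's builtin banker's rounding
would turn 1.25% into 1.2%). For a head-to-tail tandem duplication the
junction joins the sequence ending at the distal breakpoint to the
sequence starting after the proximal breakpoint, so junction
microhomology is the longest common suffix of the two flanks walking
backwards from each breakpoint; `N` never matches.

## Synthetic cohorts

The generator emulates the statistical structure of a discovery-phase
CNV screen so every stage is testable without array data, which is
rarely public for clinical cohorts:

- CNV count per genome ~ Poisson(13.3), the average reported for such
  screens (cases; controls in the motivating study averaged 12.6 — one
  shared mean keeps the generator simple since no downstream statistic
  depends on the 0.7-call difference).
- Each event is a deletion with probability r/(1+r), r = 2.1 (the
  deletion:duplication count excess).
- Lengths are log-normal parameterized by median (location = ln median,
  default medians 26.1 kb deletions / 60.8 kb duplications, σ_log = 0.9).
  The median parameterization reproduces the target medians exactly in
  expectation and gives the heavy right tail real call-length
  distributions show; σ_log = 0.9 puts ~95% of deletion lengths between
  ~4 kb and ~150 kb, a realistic spread for SNP-array calls.
- A risk duplication (default chr5:32,106,204–32,167,777) is planted per
  sample Bernoulli(0.075) in cases and Bernoulli(0.011) in controls —
  the carrier frequencies of the motivating association — with true
  diploid copy number 3/4/5 at probabilities 0.7/0.2/0.1 (most carriers
  show one extra copy; a minority amplify further).
- Events are placed uniformly over autosome lengths (GRCh37 scale),
  rejected if they fall in a reserved mask (1 Mb telomeres, 3 Mb
  centromere band) or overlap a same-type event of the same sample.
- Two callers observe each true event independently with sensitivity
  0.95, add rounded Gaussian jitter (sd 500 bp) to each boundary
  (redrawn if the interval would invert), and emit Poisson(0.5) false
  calls per sample placed outside the true events. No published
  per-caller sensitivities exist for this setting; 0.95 per caller gives
  a both-caller consensus sensitivity of ~0.90, consistent with the low
  false-negative rates qPCR validation typically finds for prioritized
  regions.
- qPCR ratios ~ Normal(true_copies/2, 0.07) truncated at 0, two assays
  per sample; sd 0.07 reflects well-behaved TaqMan replicates.

All draws flow from one `numpy.random.Generator` per stage, seeded from
`SimulationConfig.seed`, so fixed seeds give byte-identical fixtures.

What the generator does *not* model: LRR/BAF intensity signal, SNP probe
maps (jitter is probe-map-free Gaussian), HMM caller behaviour beyond
sensitivity/jitter/false-call rates, linkage between events, population
structure, or genotyping batch effects. Passing recovery tests therefore
show the analysis chain is correct under its own assumptions — not that
the callers themselves are well-calibrated on real arrays.

## Problem sizes in the test and acceptance runs

Parameter-recovery experiments use 200 replicates of n = 500/500 cohorts
(~13,000 true events each), enough for the CI-coverage fraction to be
stable to a few percent; qPCR accuracy uses one 1,000-sample panel; the
interval oracles run on 1,000 random instances with coordinates ≤ 10,000
and ≤ 50 calls, where per-base brute force is exact and fast. These sizes
were chosen so the full suite completes in minutes on one CPU while
keeping Monte-Carlo noise well below the asserted margins.

## Known limitations

- Consensus is defined for exactly two callers; voting schemes for ≥ 3
  callers are out of scope.
- Wald inference is unreliable for very sparse tables (cells < ~5); the
  zero-cell error surfaces the worst cases but small nonzero cells still
  give wide, approximate CIs — exact conditional inference is not
  implemented.
- The prioritization OR stage uses carrier counts (not chromosome
  counts); for multicopy loci these differ.
- k-means class boundaries assume the theoretical ratio spacing; strong
  assay-specific amplification bias would shift clusters and should be
  corrected upstream of this package.
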