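"""Synthetic cohorts with the statistical structure of a SNP-array CNV screen.

The generator emulates the features of a recurrent-miscarriage (RM)
case-control CNV study that downstream stages assume: roughly 13 CNV calls
per genome, a ~2.1-fold excess of deletions over duplications, log-normal
event lengths with median 26.1 kb (deletions) and 60.8 kb (duplications),
a rare risk duplication at 5p13.3 with carrier frequency ~7.5% in cases vs
~1.1% in fertile controls, two imperfect callers with boundary jitter and
caller-specific false calls, and TaqMan-style qPCR ratios clustered at
copy-number classes 2/3/4/>4.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by ``SimulationConfig.seed``, so a fixed seed reproduces output exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    CnvCall,
    Sample,
    write_cnv_calls,
    write_sample_sheet,
)

# Approximate autosome lengths (bp, GRCh37 scale) used to place events.
CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}

# Reserved mask per chromosome: 1 Mb at each telomere plus a 3 Mb band
# centred on the chromosome midpoint standing in for the centromere.
TELOMERE_BP = 1_000_000
CENTROMERE_HALF_BP = 1_500_000

CALLER_IDS = ("quantisnp", "penncnv")
ASSAY_IDS = ("assay_proximal", "assay_distal")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class RiskCnvr:
    """The planted risk duplication locus and its per-group carrier rates."""

    chrom: str = "chr5"
    start: int = 32_106_204
    end: int = 32_167_777
    carrier_freq_cases: float = 0.075
    carrier_freq_controls: float = 0.011


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the discovery-screen statistics the pipeline is
    built around: ~13.3 CNVs per genome, deletion:duplication count ratio
    2.1, median lengths 26.1 kb (del) / 60.8 kb (dup), and a risk
    duplication carried by 7.5% of cases vs 1.1% of controls.
    """

    n_cases: int = 80
    n_controls: int = 90
    n_cohort: int = 0
    mean_cnvs_per_sample: float = 13.3
    del_dup_count_ratio: float = 2.1
    median_del_len_kb: float = 26.1
    median_dup_len_kb: float = 60.8
    length_sigma_log: float = 0.9
    risk_cnvr: RiskCnvr = field(default_factory=RiskCnvr)
    caller_sensitivity: float = 0.95
    boundary_jitter_sd_bp: float = 500.0
    false_calls_per_sample: float = 0.5
    qpcr_ratio_sd: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("caller_sensitivity",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("carrier_freq_cases", "carrier_freq_controls"):
            v = getattr(self.risk_cnvr, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"risk_cnvr.{name} must be in [0, 1], got {v}")
        if self.median_del_len_kb <= 0 or self.median_dup_len_kb <= 0:
            raise ConfigError("median lengths must be > 0")
        if self.mean_cnvs_per_sample < 0 or self.false_calls_per_sample < 0:
            raise ConfigError("rates must be >= 0")
        if self.del_dup_count_ratio < 0:
            raise ConfigError("del_dup_count_ratio must be >= 0")
        chrom = self.risk_cnvr.chrom
        if chrom not in CHROM_LENGTHS:
            raise ConfigError(f"risk locus chromosome {chrom!r} not in genome model")
        if _in_mask(chrom, self.risk_cnvr.start, self.risk_cnvr.end):
            raise ConfigError("risk locus overlaps the telomere/centromere mask")


@dataclass(frozen=True)
class TrueCnvProfile:
    """Ground-truth CNV events of one simulated genome.

    ``events`` are (chrom, start, end, cnv_type, true_copy_number) tuples,
    non-overlapping within a sample per type.
    """

    sample_id: str
    events: tuple[tuple[str, int, int, str, int], ...]

    def risk_copy_number(self, locus: RiskCnvr) -> int:
        """Diploid copy number at the risk locus (2 if no event spans it)."""
        for chrom, start, end, cnv_type, cn in self.events:
            if chrom == locus.chrom and start <= locus.end and end >= locus.start:
                if cnv_type == "duplication":
                    return cn
        return 2


def _in_mask(chrom: str, start: int, end: int) -> bool:
    length = CHROM_LENGTHS[chrom]
    if start <= TELOMERE_BP or end > length - TELOMERE_BP:
        return True
    mid = length // 2
    return start <= mid + CENTROMERE_HALF_BP and end >= mid - CENTROMERE_HALF_BP


def _overlaps_any(
    events: list[tuple[str, int, int, str, int]],
    chrom: str,
    start: int,
    end: int,
    cnv_type: str | None = None,
) -> bool:
    for c, s, e, t, _ in events:
        if c != chrom:
            continue
        if cnv_type is not None and t != cnv_type:
            continue
        if start <= e and end >= s:
            return True
    return False


_CHROMS = tuple(CHROM_LENGTHS)
_CHROM_WEIGHTS = np.array([CHROM_LENGTHS[c] for c in _CHROMS], dtype=float)
_CHROM_WEIGHTS /= _CHROM_WEIGHTS.sum()

# Copy-number spectrum of planted risk duplications; most carriers have a
# single extra copy, a minority show 4 or >4 diploid copies.
_RISK_CN_VALUES = (3, 4, 5)
_RISK_CN_PROBS = (0.7, 0.2, 0.1)


def _draw_event(
    rng: np.random.Generator,
    config: SimulationConfig,
    existing: list[tuple[str, int, int, str, int]],
) -> tuple[str, int, int, str, int]:
    """One background CNV: type, log-normal length, uniform placement.

    Placement avoids the telomere/centromere mask and same-type overlap
    with events already drawn for the sample (rejection sampling).
    """
    r = config.del_dup_count_ratio
    p_del = r / (1.0 + r) if r > 0 else 0.0
    for _ in range(1000):
        is_del = rng.random() < p_del
        cnv_type = "deletion" if is_del else "duplication"
        median_bp = (
            config.median_del_len_kb if is_del else config.median_dup_len_kb
        ) * 1000.0
        length = int(
            round(median_bp * np.exp(rng.normal(0.0, config.length_sigma_log)))
        )
        length = max(length, 51)  # CNVs are defined as >50 bp events
        chrom = _CHROMS[rng.choice(len(_CHROMS), p=_CHROM_WEIGHTS)]
        max_start = CHROM_LENGTHS[chrom] - length
        if max_start < 1:
            continue
        start = int(rng.integers(1, max_start + 1))
        end = start + length - 1
        if _in_mask(chrom, start, end):
            continue
        if _overlaps_any(existing, chrom, start, end, cnv_type):
            continue
        cn = 1 if is_del else 3
        return (chrom, start, end, cnv_type, cn)
    raise RuntimeError("failed to place a CNV event after 1000 attempts")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Sample], list[TrueCnvProfile]]:
    """Draw samples and their ground-truth CNV profiles.

    Per-sample CNV counts are Poisson; each event is a deletion with
    probability r/(1+r) for r the deletion:duplication count ratio; lengths
    are log-normal with the configured medians.  Risk-locus carriership is
    Bernoulli per group; carriers receive a duplication spanning the locus
    with true diploid copy number drawn from {3, 4, >4}.
    """
    rng = np.random.default_rng(config.seed)
    locus = config.risk_cnvr

    samples: list[Sample] = []
    for i in range(config.n_cases):
        subtype = "primary_rm" if i % 2 == 0 else "secondary_rm"
        samples.append(Sample(f"RM-F{i + 1}", "female", "case", subtype, "EE"))
    for i in range(config.n_controls):
        samples.append(Sample(f"FFC{i + 1}", "female", "fertile_control", "none", "EE"))
    for i in range(config.n_cohort):
        sex = "female" if i % 2 == 0 else "male"
        samples.append(Sample(f"COH{i + 1}", sex, "cohort", "none", "EE"))

    profiles: list[TrueCnvProfile] = []
    for sample in samples:
        events: list[tuple[str, int, int, str, int]] = []
        p_carrier = (
            locus.carrier_freq_cases
            if sample.group == "case"
            else locus.carrier_freq_controls
        )
        if rng.random() < p_carrier:
            cn = int(rng.choice(_RISK_CN_VALUES, p=_RISK_CN_PROBS))
            events.append((locus.chrom, locus.start, locus.end, "duplication", cn))
        n_background = int(rng.poisson(config.mean_cnvs_per_sample))
        for _ in range(n_background):
            ev = _draw_event(rng, config, events)
            # background duplications must not confound the risk locus
            if (
                ev[0] == locus.chrom
                and ev[1] <= locus.end
                and ev[2] >= locus.start
            ):
                continue
            events.append(ev)
        events.sort(key=lambda e: (e[0], e[1]))
        profiles.append(TrueCnvProfile(sample.sample_id, tuple(events)))
    return samples, profiles


def simulate_caller_observations(
    profiles: Sequence[TrueCnvProfile],
    config: SimulationConfig,
    caller_ids: tuple[str, str] = CALLER_IDS,
) -> list[CnvCall]:
    """Two-caller observations of the true profiles.

    Each caller sees each true event independently with probability
    ``caller_sensitivity``; observed boundaries get independent rounded
    Gaussian jitter (redrawn when it would invert the interval); each
    caller adds Poisson-many false calls per sample placed uniformly
    outside the sample's true events.
    """
    if len(set(caller_ids)) != 2:
        raise ConfigError("exactly two distinct caller ids are required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sd = config.boundary_jitter_sd_bp
    calls: list[CnvCall] = []
    for profile in profiles:
        events = list(profile.events)
        for caller in caller_ids:
            for chrom, start, end, cnv_type, cn in events:
                if rng.random() >= config.caller_sensitivity:
                    continue
                for _ in range(100):
                    obs_start = max(1, start + int(round(rng.normal(0.0, sd))))
                    obs_end = end + int(round(rng.normal(0.0, sd)))
                    if obs_start <= obs_end:
                        break
                else:  # pragma: no cover - requires sd >> length
                    obs_start, obs_end = start, end
                calls.append(
                    CnvCall(
                        sample_id=profile.sample_id,
                        caller_id=caller,
                        chrom=chrom,
                        start=obs_start,
                        end=obs_end,
                        cnv_type=cnv_type,
                        copy_number=cn,
                        confidence=float(np.round(rng.uniform(10.0, 100.0), 2)),
                    )
                )
            n_false = int(rng.poisson(config.false_calls_per_sample))
            for _ in range(n_false):
                for _ in range(1000):
                    ev = _draw_event(rng, config, [])
                    if not _overlaps_any(events, ev[0], ev[1], ev[2]):
                        break
                else:  # pragma: no cover
                    continue
                chrom, start, end, cnv_type, cn = ev
                calls.append(
                    CnvCall(
                        sample_id=profile.sample_id,
                        caller_id=caller,
                        chrom=chrom,
                        start=start,
                        end=end,
                        cnv_type=cnv_type,
                        copy_number=cn,
                        confidence=float(np.round(rng.uniform(10.0, 100.0), 2)),
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.caller_id))
    return calls


def simulate_qpcr_panel(
    samples: Sequence[Sample],
    profiles: Sequence[TrueCnvProfile],
    config: SimulationConfig,
    assay_ids: tuple[str, str] = ASSAY_IDS,
):
    """TaqMan-style qPCR ratios at the risk locus, two assays per sample.

    Ratios are Normal(true_copies / 2, qpcr_ratio_sd) truncated at zero
    (negative draws are redrawn).  Returns a pandas DataFrame with columns
    sample_id, assay_id, ratio.
    """
    import pandas as pd

    if len(set(assay_ids)) != 2:
        raise ConfigError("exactly two distinct assay ids are required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    by_id = {p.sample_id: p for p in profiles}
    rows = []
    for sample in samples:
        profile = by_id[sample.sample_id]
        true_cn = profile.risk_copy_number(config.risk_cnvr)
        for assay in assay_ids:
            ratio = rng.normal(true_cn / 2.0, config.qpcr_ratio_sd)
            while ratio < 0.0:
                ratio = rng.normal(true_cn / 2.0, config.qpcr_ratio_sd)
            rows.append((sample.sample_id, assay, float(ratio)))
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "ratio"])


def write_fixture_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write the pipeline's input TSVs plus a truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples, profiles = simulate_cohort(config)
    calls = simulate_caller_observations(profiles, config)
    qpcr = simulate_qpcr_panel(samples, profiles, config)

    paths = {
        "samples": out_dir / "samples.tsv",
        "calls": out_dir / "calls.tsv",
        "qpcr": out_dir / "qpcr.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_sample_sheet(samples, paths["samples"])
    write_cnv_calls(calls, paths["calls"])
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    with paths["truth"].open("w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcnv_type\ttrue_copy_number\n")
        for p in profiles:
            for chrom, start, end, cnv_type, cn in p.events:
                fh.write(f"{p.sample_id}\t{chrom}\t{start}\t{end}\t{cnv_type}\t{cn}\n")
    return paths
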