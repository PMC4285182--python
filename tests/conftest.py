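import numpy as np
import pytest

from cnvr_assoc import (
    SimulationConfig,
    simulate_caller_observations,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noiseless cohort: observations equal the truth exactly."""
    config = SimulationConfig(
        n_cases=20,
        n_controls=20,
        caller_sensitivity=1.0,
        boundary_jitter_sd_bp=0.0,
        false_calls_per_sample=0.0,
        seed=11,
    )
    samples, profiles = simulate_cohort(config)
    calls = simulate_caller_observations(profiles, config)
    return config, samples, profiles, calls


def random_calls(rng: np.random.Generator, n_calls: int, max_coord: int = 10_000,
                 max_len: int = 200, n_samples: int = 4):
    """Random small CNV calls for brute-force oracle comparisons."""
    from cnvr_assoc import CnvCall

    calls = []
    for _ in range(n_calls):
        start = int(rng.integers(1, max_coord))
        length = int(rng.integers(1, max_len + 1))
        cnv_type = "deletion" if rng.random() < 0.5 else "duplication"
        calls.append(
            CnvCall(
                sample_id=f"S{int(rng.integers(1, n_samples + 1))}",
                caller_id="quantisnp" if rng.random() < 0.5 else "penncnv",
                chrom=f"chr{int(rng.integers(1, 3))}",
                start=start,
                end=start + length - 1,
                cnv_type=cnv_type,
            )
        )
    return calls


def consensus_base_oracle(calls):
    """Per-base truth: a base is consensus iff covered by both callers with
    the same type for the same sample."""
    cover: dict[tuple, set] = {}
    for c in calls:
        for pos in range(c.start, c.end + 1):
            cover.setdefault((c.sample_id, c.chrom, c.cnv_type, pos), set()).add(
                c.caller_id
            )
    return {key for key, callers in cover.items() if len(callers) >= 2}


def consensus_bases(consensus_calls):
    bases = set()
    for c in consensus_calls:
        for pos in range(c.start, c.end + 1):
            bases.add((c.sample_id, c.chrom, c.cnv_type, pos))
    return bases
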