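"""Fixed-effects meta-analysis of per-stratum carrier associations.

Two schemes are provided.  Inverse-variance weighting combines the
per-stratum log odds ratios: beta = sum(w_i beta_i) / sum(w_i) with
w_i = 1/se_i^2 and combined se = 1/sqrt(sum w_i).  The sample-size
weighted z-score scheme (the METAL convention) combines signed
z-statistics: z = sum(w_i z_i) / sqrt(sum w_i^2) with w_i = sqrt(n_eff_i)
and effective sample size n_eff = 4 / (1/n_cases + 1/n_controls), which
corrects for asymmetric case/control ratios.  Stratum z-values are taken
directly as beta_i/se_i rather than re-derived from rounded printed
P-values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .assoc import AssociationResult, Z975


@dataclass(frozen=True)
class MetaResult:
    method: str  # inverse_variance | weighted_z
    beta: float | None
    se: float | None
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    z: float
    p: float
    weights: tuple[float, ...]
    n_eff: tuple[float, ...] | None = None


def meta_inverse_variance(results: Sequence[AssociationResult]) -> MetaResult:
    """Fixed-effects inverse-variance combination of log odds ratios."""
    if not results:
        raise ValueError("at least one stratum result is required")
    if any(r.se <= 0 for r in results):
        raise ValueError("all standard errors must be > 0")
    weights = tuple(1.0 / r.se**2 for r in results)
    total = sum(weights)
    beta = sum(w * r.beta for w, r in zip(weights, results)) / total
    se = total**-0.5
    z = beta / se
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return MetaResult(
        method="inverse_variance",
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
        z=z,
        p=p,
        weights=weights,
    )


def effective_sample_size(
    n_cases: int, n_controls: int, convention: str = "metal"
) -> float:
    """Per-stratum effective sample size.

    ``'metal'`` uses 4/(1/n_cases + 1/n_controls), down-weighting strata
    with asymmetric case/control ratios; ``'total'`` uses
    n_cases + n_controls.
    """
    if convention == "metal":
        if n_cases <= 0 or n_controls <= 0:
            raise ValueError("group sizes must be > 0")
        return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    if convention == "total":
        return float(n_cases + n_controls)
    raise ValueError(f"unknown effective-sample-size convention {convention!r}")


def meta_weighted_z(
    results: Sequence[AssociationResult],
    n_cases: Sequence[int],
    n_controls: Sequence[int],
    ess_convention: str = "metal",
) -> MetaResult:
    """Sample-size weighted z-score combination of stratum associations."""
    if not results:
        raise ValueError("at least one stratum result is required")
    if not len(results) == len(n_cases) == len(n_controls):
        raise ValueError("results, n_cases and n_controls must have equal length")
    for r in results:
        if r.p <= 0.0 or r.p >= 1.0:
            raise ValueError(
                f"stratum {r.stratum_label!r}: p={r.p} leaves the z-score undefined"
            )
    n_eff = tuple(
        effective_sample_size(nc, nk, ess_convention)
        for nc, nk in zip(n_cases, n_controls)
    )
    weights = tuple(math.sqrt(n) for n in n_eff)
    z_values = [r.beta / r.se for r in results]
    z = sum(w * zi for w, zi in zip(weights, z_values)) / math.sqrt(
        sum(w**2 for w in weights)
    )
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return MetaResult(
        method="weighted_z",
        beta=None,
        se=None,
        or_=None,
        ci_low=None,
        ci_high=None,
        z=z,
        p=p,
        weights=weights,
        n_eff=n_eff,
    )
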