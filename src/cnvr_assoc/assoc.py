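"""Carrier-vs-noncarrier association for one stratum from a 2x2 table.

For a table with ``a`` carriers among cases, ``b`` noncarriers among
cases, ``c`` carriers among controls and ``d`` noncarriers among
controls, the log odds ratio is beta = ln(ad / bc) with large-sample
standard error se = sqrt(1/a + 1/b + 1/c + 1/d) (Woolf).  Wald inference
(z = beta/se, 95% CI = exp(beta +/- 1.96 se)) is numerically equivalent
to maximum-likelihood logistic regression of case status on carrier
status, which is how such tables are analysed in practice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from ._util import round_half_up

Z975 = float(norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b = carriers/noncarriers among cases, c/d among controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_carriers(
        cls,
        n_cases: int,
        carriers_cases: int,
        n_controls: int,
        carriers_controls: int,
    ) -> "ContingencyTable":
        if carriers_cases > n_cases or carriers_controls > n_controls:
            raise ValueError("carrier count exceeds group size")
        return cls(
            a=carriers_cases,
            b=n_cases - carriers_cases,
            c=carriers_controls,
            d=n_controls - carriers_controls,
        )

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    stratum_label: str = ""


def carrier_frequency(n_carriers: int, n_total: int) -> float:
    """Carrier percentage rounded half-up to one decimal (table style)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_carriers <= n_total:
        raise ValueError("n_carriers must be in [0, n_total]")
    return round_half_up(100.0 * n_carriers / n_total, 1)


def association_2x2(
    table: ContingencyTable,
    zero_cell_policy: str = "error",
    stratum_label: str = "",
) -> AssociationResult:
    """Wald odds-ratio inference on a carrier 2x2 table.

    With ``zero_cell_policy='error'`` a zero cell raises (a silent
    continuity correction would be invisible bias); with ``'haldane'``,
    0.5 is added to every cell when any cell is zero.
    """
    if zero_cell_policy not in {"error", "haldane"}:
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    zero = [name for name, v in cells.items() if v == 0]
    if zero:
        if zero_cell_policy == "error":
            raise ValueError(
                f"zero cell(s) {zero} in 2x2 table; use zero_cell_policy='haldane'"
            )
        a, b, c, d = (v + 0.5 for v in cells.values())
    else:
        a, b, c, d = (float(v) for v in cells.values())

    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = beta / se
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return AssociationResult(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
        z=z,
        p=p,
        stratum_label=stratum_label,
    )
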