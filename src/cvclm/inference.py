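"""Statistical layer: rate and incidence comparisons, NNR, sample size.

* ``n1_chi_squared`` — the "N−1" χ² test for 2×2 comparisons of proportions:
  Pearson's statistic multiplied by (N−1)/N, referred to χ²(1).
* ``rate_z_test`` — incidence-density comparison under the Poisson normal
  approximation: z = (r_a − r_b) / sqrt(e_a/d_a² + e_b/d_b²).
* ``nnr`` — number of catheters needed to be removed to prevent one CRBSI:
  the ceiling of the reciprocal of the absolute rate difference.
* ``sample_size_two_proportions`` — normal-approximation two-proportion
  sample size (pooled- or unpooled-variance variant, no continuity
  correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .landmark import CRBSI_DEFINITIONS, EndpointResult
from .randomization import ARMS, CONTROL_ARM

__all__ = [
    "ComparisonResult",
    "PowerSpec",
    "InferenceError",
    "n1_chi_squared",
    "rate_z_test",
    "nnr",
    "sample_size_two_proportions",
    "platelet_below_threshold",
    "build_results_table",
]


class InferenceError(ValueError):
    """Raised for undefined statistics or invalid specifications."""


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group comparison: test statistic, p-value and the inputs."""

    statistic_name: str  # "n1_chi2" or "rate_z"
    statistic_value: float
    p_value: float
    arm_summary: Optional[EndpointResult] = None
    control_summary: Optional[EndpointResult] = None


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-proportion sample-size calculation."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.8
    allocation_ratio: float = 1.0  # n2 / n1

    def validate(self) -> None:
        if not (0 < self.p2 < self.p1 < 1):
            raise InferenceError("proportions must satisfy 0 < p2 < p1 < 1")
        if not 0 < self.alpha < 1:
            raise InferenceError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise InferenceError("power must be in (0, 1)")
        if self.allocation_ratio <= 0:
            raise InferenceError("allocation_ratio must be > 0")


def n1_chi_squared(events_a: int, n_a: int, events_b: int, n_b: int,
                   arm_summary: Optional[EndpointResult] = None,
                   control_summary: Optional[EndpointResult] = None) -> ComparisonResult:
    """The "N−1" χ² test of two proportions.

    Pearson's χ² of the 2×2 table (events / non-events by group) multiplied
    by (N−1)/N, with p from χ²(1).  Symmetric in group order.  A zero margin
    (no events at all, or no non-events at all) leaves the statistic
    undefined and raises.
    """
    for e, n in ((events_a, n_a), (events_b, n_b)):
        if not 0 <= e <= n:
            raise InferenceError(f"events must satisfy 0 <= events <= n, got {e}/{n}")
    N = n_a + n_b
    if N < 2:
        raise InferenceError("need at least two observations in total")
    a, b = events_a, n_a - events_a
    c, d = events_b, n_b - events_b
    col_events, col_none = a + c, b + d
    if col_events == 0 or col_none == 0:
        raise InferenceError(
            "zero margin: all observations fall in one outcome column, "
            "the chi-squared statistic is undefined"
        )
    pearson = N * (a * d - b * c) ** 2 / (n_a * n_b * col_events * col_none)
    statistic = pearson * (N - 1) / N
    p = float(stats.chi2.sf(statistic, df=1))
    return ComparisonResult("n1_chi2", float(statistic), p,
                            arm_summary=arm_summary, control_summary=control_summary)


def rate_z_test(events_a: int, days_a: float, events_b: int, days_b: float,
                arm_summary: Optional[EndpointResult] = None,
                control_summary: Optional[EndpointResult] = None) -> ComparisonResult:
    """z test for a difference of incidence densities.

    Poisson normal approximation on the rate difference; the variance of
    each rate e/d is estimated by e/d².  Two-sided p.  Undefined (raises)
    when both event counts are zero.
    """
    if days_a <= 0 or days_b <= 0:
        raise InferenceError("person-time denominators must be > 0")
    if events_a < 0 or events_b < 0:
        raise InferenceError("event counts must be >= 0")
    if events_a + events_b == 0:
        raise InferenceError("z statistic undefined: no events in either group")
    r_a, r_b = events_a / days_a, events_b / days_b
    se = math.sqrt(events_a / days_a ** 2 + events_b / days_b ** 2)
    z = (r_a - r_b) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ComparisonResult("rate_z", float(z), p,
                            arm_summary=arm_summary, control_summary=control_summary)


def nnr(events_control: int, events_arm: int, n_per_arm: int) -> int:
    """Number of catheters needed to be removed to prevent one CRBSI.

    The absolute rate difference between control and a removal arm (equal
    arm sizes) is inverted and rounded up: NNR = ceil(n / (e_c − e_a)).
    Undefined when the removal arm has at least as many events as control.
    """
    if n_per_arm < 1:
        raise InferenceError("n_per_arm must be >= 1")
    if events_control <= events_arm:
        raise InferenceError(
            "NNR undefined: control events must exceed arm events "
            f"(got control {events_control} <= arm {events_arm})"
        )
    return math.ceil(n_per_arm / (events_control - events_arm))


def sample_size_two_proportions(spec: PowerSpec, variant: str = "pooled") -> int:
    """Per-group n for a two-sided two-proportion z test (normal approx).

    ``variant="pooled"`` uses the pooled variance under H0 in the alpha term
    (the classical formulation); ``"unpooled"`` uses the alternative's
    variance in both terms.  No continuity correction.  Returns the smallest
    integer n for group 1 (group 2 has ``allocation_ratio``×n).
    """
    spec.validate()
    if variant not in ("pooled", "unpooled"):
        raise InferenceError("variant must be 'pooled' or 'unpooled'")
    p1, p2, r = spec.p1, spec.p2, spec.allocation_ratio
    q1, q2 = 1 - p1, 1 - p2
    delta = p1 - p2
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    var_alt = p1 * q1 + p2 * q2 / r
    if variant == "pooled":
        pbar = (p1 + r * p2) / (1 + r)
        qbar = 1 - pbar
        n = (z_a * math.sqrt((1 + 1 / r) * pbar * qbar) + z_b * math.sqrt(var_alt)) ** 2 / delta ** 2
    else:
        n = (z_a + z_b) ** 2 * var_alt / delta ** 2
    return math.ceil(n - 1e-12)


def platelet_below_threshold(counts: Sequence[float], threshold: float,
                             ) -> tuple[float, int, int]:
    """Fraction (and n/N) of platelet counts strictly below a threshold."""
    counts = list(counts)
    if not counts:
        raise InferenceError("empty platelet count list")
    if threshold <= 0:
        raise InferenceError("threshold must be > 0")
    below = sum(1 for c in counts if c < threshold)
    return below / len(counts), below, len(counts)


def build_results_table(endpoints: Iterable[EndpointResult],
                        comparisons: Iterable[ComparisonResult],
                        nnrs: Mapping[tuple[str, str], Optional[int]],
                        ) -> pd.DataFrame:
    """Assemble the outcome table: one row per (definition, arm).

    Columns: n, events, CVC days, rate %, incidence /1000 d, the p-values of
    both tests versus control, and the NNR.  Control rows carry no p/NNR
    cells (self-comparison is undefined).  Raises if a definition class has
    no control arm.
    """
    endpoints = list(endpoints)
    by_def: dict[str, dict[str, EndpointResult]] = {}
    for ep in endpoints:
        by_def.setdefault(ep.crbsi_definition, {})[ep.arm] = ep
    for definition, arms in by_def.items():
        if CONTROL_ARM not in arms:
            raise InferenceError(
                f"missing {CONTROL_ARM} arm for definition {definition!r}"
            )
        if len(arms) < 2:
            raise InferenceError(
                f"definition {definition!r} needs at least one removal arm"
            )

    pvals: dict[tuple[str, str, str], float] = {}
    for comp in comparisons:
        if comp.arm_summary is None:
            continue
        key = (comp.arm_summary.crbsi_definition, comp.arm_summary.arm,
               comp.statistic_name)
        pvals[key] = comp.p_value

    rows = []
    for definition in CRBSI_DEFINITIONS:
        if definition not in by_def:
            continue
        arms = by_def[definition]
        for arm in ARMS:
            if arm not in arms:
                continue
            ep = arms[arm]
            is_control = arm == CONTROL_ARM
            rows.append({
                "crbsi_definition": definition,
                "arm": arm,
                "n_cvc": ep.n_cvc,
                "events": ep.events,
                "cvc_days": ep.cvc_days,
                "rate_percent": ep.rate_percent,
                "incidence_per_1000": ep.incidence_per_1000,
                "p_rate_n1_chi2": None if is_control else pvals.get((definition, arm, "n1_chi2")),
                "p_incidence_z": None if is_control else pvals.get((definition, arm, "rate_z")),
                "nnr": None if is_control else nnrs.get((definition, arm)),
            })
    return pd.DataFrame(rows)
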