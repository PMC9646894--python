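"""Between-cohort incremental cost-effectiveness (real-terms local currency).

Compares two diagnosis-year cohorts (e.g. the first and last accrual
years) on median real-terms cost and 3-year overall survival: the ICER is
the change in cost per unit change in survival fraction.  Three-year OS
is the effectiveness measure because the later cohort has only completed
three years of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortSummary", "IcerResult", "icer", "percent_change"]


class IcerDomainError(ValueError):
    """Invalid ICER input."""


@dataclass(frozen=True)
class CohortSummary:
    """One diagnosis-year cohort: median real-terms cost and 3-year OS."""

    year: int
    median_cost: float
    os3: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.os3 <= 1.0:
            raise IcerDomainError(f"os3={self.os3} outside [0, 1]")
        if self.median_cost < 0:
            raise IcerDomainError("negative median cost")


@dataclass(frozen=True)
class IcerResult:
    """ICER value plus the cost-effectiveness-plane quadrant label."""

    icer: float
    delta_cost: float
    delta_os3: float
    quadrant: str


def icer(baseline: CohortSummary, comparator: CohortSummary) -> IcerResult:
    """Incremental cost per unit gain in 3-year survival fraction.

    ``(cost2 - cost1) / (os3_2 - os3_1)``; the quadrant label reports the
    sign pattern ("dominant" = cheaper and more effective, "dominated" =
    costlier and less effective).
    """
    d_cost = comparator.median_cost - baseline.median_cost
    d_eff = comparator.os3 - baseline.os3
    if d_eff == 0.0:
        raise IcerDomainError("equal 3-year OS: ICER undefined")
    if d_cost >= 0 and d_eff > 0:
        quadrant = "more costly, more effective"
    elif d_cost < 0 and d_eff > 0:
        quadrant = "dominant (less costly, more effective)"
    elif d_cost >= 0 and d_eff < 0:
        quadrant = "dominated (more costly, less effective)"
    else:
        quadrant = "less costly, less effective"
    return IcerResult(
        icer=d_cost / d_eff, delta_cost=d_cost, delta_os3=d_eff, quadrant=quadrant
    )


def percent_change(v1: float, v2: float) -> float:
    """Percent change from ``v1`` to ``v2``: ``100 (v2 - v1) / v1``."""
    if v1 == 0:
        raise IcerDomainError("percent change undefined from a zero base")
    return 100.0 * (v2 - v1) / v1
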