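"""Disability-adjusted life years averted by childhood cancer treatment.

The model compares each treated child with an untreated counterfactual who
does not survive the cancer.  Effectiveness is the 5-year overall survival
fraction ``S``, used as a cure proxy.  The burden averted per patient is

    DALYs averted = DALYs(no treatment) - DALYs(treatment),

with years of life lost (YLL) and years lived with disability (YLD)
discounted continuously at rate ``r``: a life-year stream of length ``L``
contributes ``(1 - exp(-r L)) / r`` discounted year-equivalents.

Arm construction
----------------
* Untreated children who would have been cured by treatment die at
  diagnosis, losing their full remaining life expectancy ``LE - a``.
* Children who die despite treatment die at a mean time ``delta`` from
  diagnosis; the same death time is applied to their untreated
  counterfactual, so these patients contribute only the treatment
  disability term to DALYs averted (treatment neither gains nor loses
  them life-years, it only adds time spent under therapy).
* Cured patients carry a disability weight ``dw_tx`` during the
  ``tx_duration`` treatment years, then a lifelong utility decrement
  ``d_late`` for late-effect morbidity, over a residual life expectancy
  reduced by the fraction ``le_reduction`` for excess late mortality.
  The life-years lost to that reduction enter as YLL.

Dividing a per-patient cost by the DALYs averted gives the
cost-effectiveness ratio, classified against WHO-CHOICE thresholds
relative to GDP per capita.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import optimize

__all__ = [
    "DalyParams",
    "DalyResult",
    "D_LATE_DEFAULT",
    "LE_REDUCTION_DEFAULT",
    "LIFE_EXPECTANCY_DEFAULT",
    "GDP_PER_CAPITA_DEFAULT",
    "discounted_years",
    "dalys_no_treatment",
    "dalys_averted",
    "cost_per_daly",
    "who_choice_classify",
    "evaluate",
    "sensitivity_grid",
    "calibrate_adjustments",
]

#: Life expectancy at birth in Egypt (years, 2020 vintage).
LIFE_EXPECTANCY_DEFAULT = 72.06

#: GDP per capita in Egypt (USD, 2019) — the WHO-CHOICE denominator.
GDP_PER_CAPITA_DEFAULT = 3019.0

#: Lifelong utility decrement for cured patients (late-effect morbidity)
#: and fractional reduction of remaining life expectancy (excess late
#: mortality).  The underlying per-condition values are not published with
#: the source cohort, so these defaults are calibrated once, via
#: :func:`calibrate_adjustments`, to the all-cancers cost/DALY pair
#: ($1384 at 3% discount, $2347 at 6%).  They are model assumptions, not
#: measured quantities; override them per analysis where better data exist.
D_LATE_DEFAULT = 0.2836
LE_REDUCTION_DEFAULT = 0.1290


class DalyDomainError(ValueError):
    """Parameter combination outside the model's domain."""


def discounted_years(L: float, r: float) -> float:
    """Discounted year-equivalents of a life-year stream of length ``L``.

    Continuous (exponential) discounting: ``int_0^L e^{-rt} dt``, which is
    ``L`` when ``r == 0`` and ``(1 - e^{-rL})/r`` otherwise.  Strictly
    decreasing in ``r`` for ``L > 0``.
    """
    if L < 0:
        raise DalyDomainError(f"negative horizon L={L}")
    if r < 0:
        raise DalyDomainError(f"negative discount rate r={r}")
    if r == 0:
        return float(L)
    # expm1 keeps full precision as r -> 0
    return -math.expm1(-r * L) / r


@dataclass(frozen=True)
class DalyParams:
    """All inputs of the DALYs-averted model for one patient group.

    Parameters
    ----------
    age_at_dx : mean age at diagnosis, years.
    os5 : 5-year overall survival fraction, used as the cure proxy.
    life_expectancy : general-population life expectancy, years.
    discount_rate : per-year continuous discount rate.
    tx_duration : years under active treatment (disability ``dw_tx``).
    dw_tx : disability weight during treatment, in [0, 1).
    d_late : lifelong utility decrement for cured patients, in [0, 1).
    le_reduction : fractional reduction of remaining life expectancy for
        excess late mortality (0 in the base case toggles, 0.15/0.30 in
        sensitivity analyses).
    death_time : mean years from diagnosis to death for non-survivors;
        applied identically in the treated and untreated arms.
    """

    age_at_dx: float
    os5: float
    life_expectancy: float = LIFE_EXPECTANCY_DEFAULT
    discount_rate: float = 0.03
    tx_duration: float = 2.0
    dw_tx: float = 0.20
    d_late: float = D_LATE_DEFAULT
    le_reduction: float = LE_REDUCTION_DEFAULT
    death_time: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.os5 <= 1.0:
            raise DalyDomainError(f"os5={self.os5} outside [0, 1]")
        if self.discount_rate < 0:
            raise DalyDomainError("negative discount rate")
        if not 0.0 <= self.dw_tx < 1.0 or not 0.0 <= self.d_late < 1.0:
            raise DalyDomainError("disability weights must lie in [0, 1)")
        if not 0.0 <= self.le_reduction < 1.0:
            raise DalyDomainError("le_reduction must lie in [0, 1)")
        if self.age_at_dx >= self.life_expectancy:
            raise DalyDomainError(
                f"age at diagnosis {self.age_at_dx} >= life expectancy "
                f"{self.life_expectancy}"
            )
        if not 0.0 <= self.death_time <= 5.0:
            raise DalyDomainError("death_time must lie in [0, 5] years")
        if self.tx_duration < 0:
            raise DalyDomainError("negative treatment duration")


@dataclass
class DalyResult:
    """Decomposition of DALYs averted plus the cost-effectiveness verdict."""

    dalys_no_tx: float
    dalys_tx: float
    dalys_averted: float
    cost_per_daly: float | None = None
    gdp_ratio: float | None = None
    classification: str | None = None


def dalys_no_treatment(p: DalyParams) -> float:
    """Untreated burden at diagnosis: full remaining discounted life lost.

    Assumes an untreated child does not survive the cancer; returns
    ``discounted_years(LE - a, r)``.
    """
    return discounted_years(p.life_expectancy - p.age_at_dx, p.discount_rate)


def dalys_averted(p: DalyParams) -> DalyResult:
    """Per-patient DALYs in each arm and the difference (DALYs averted).

    Raises
    ------
    DalyDomainError
        If the reduced residual lifespan ``(1 - le_reduction)(LE - a)`` is
        shorter than the treatment duration.
    """
    r = p.discount_rate
    L = p.life_expectancy - p.age_at_dx
    L_red = (1.0 - p.le_reduction) * L
    if L_red < p.tx_duration:
        raise DalyDomainError(
            f"reduced lifespan {L_red:.2f} y shorter than treatment "
            f"duration {p.tx_duration} y"
        )
    S, delta, T = p.os5, p.death_time, p.tx_duration

    # Survivor (cured) arm: treatment YLD, lifelong late-effect YLD over
    # the reduced lifespan, and YLL from the life-expectancy reduction.
    yld_tx = p.dw_tx * discounted_years(T, r)
    yld_late = p.d_late * math.exp(-r * T) * discounted_years(L_red - T, r)
    yll_reduction = discounted_years(L, r) - discounted_years(L_red, r)
    tx_survivor = yld_tx + yld_late + yll_reduction

    # Non-survivor: dies at delta with treatment disability up to then.
    yll_death = math.exp(-r * delta) * discounted_years(L - delta, r)
    tx_nonsurvivor = p.dw_tx * discounted_years(delta, r) + yll_death

    dalys_tx = S * tx_survivor + (1.0 - S) * tx_nonsurvivor
    # Untreated counterfactual: would-be survivors die at diagnosis;
    # would-be non-survivors die at the same delta (no extra life-years
    # attributed to a treatment that does not save them).
    dalys_no_tx = S * discounted_years(L, r) + (1.0 - S) * yll_death

    return DalyResult(
        dalys_no_tx=dalys_no_tx,
        dalys_tx=dalys_tx,
        dalys_averted=dalys_no_tx - dalys_tx,
    )


def cost_per_daly(cost: float, averted: float) -> float:
    """Cost-effectiveness ratio: cost per DALY averted."""
    if averted <= 0:
        raise DalyDomainError(
            f"cost per DALY undefined for {averted} DALYs averted"
        )
    return cost / averted


def who_choice_classify(ratio: float) -> str:
    """WHO-CHOICE classification of a cost/DALY-to-GDP-per-capita ratio.

    ratio < 1: very cost-effective; 1 <= ratio < 3: cost-effective;
    ratio >= 3: not cost-effective.  Boundary ratios take the less
    favourable label.
    """
    if ratio < 0:
        raise DalyDomainError(f"negative GDP ratio {ratio}")
    if ratio < 1.0:
        return "very cost-effective"
    if ratio < 3.0:
        return "cost-effective"
    return "not cost-effective"


def evaluate(
    p: DalyParams,
    cost: float,
    gdp_per_capita: float = GDP_PER_CAPITA_DEFAULT,
) -> DalyResult:
    """Full per-group evaluation: DALYs averted, cost/DALY, WHO verdict."""
    res = dalys_averted(p)
    res.cost_per_daly = cost_per_daly(cost, res.dalys_averted)
    res.gdp_ratio = res.cost_per_daly / gdp_per_capita
    res.classification = who_choice_classify(res.gdp_ratio)
    return res


def sensitivity_grid(
    p: DalyParams,
    cost: float,
    gdp_per_capita: float = GDP_PER_CAPITA_DEFAULT,
    rates: Sequence[float] = (0.0, 0.03, 0.06),
    reductions: Sequence[float] = (0.0, 0.15, 0.30),
    decrement_toggle: Sequence[bool] = (True, False),
) -> pd.DataFrame:
    """Two-way deterministic sensitivity analysis.

    Crosses discount rates with life-expectancy reductions and an on/off
    toggle for the late-effect utility decrement; every cell is an
    independent :func:`dalys_averted` evaluation.
    """
    rows = []
    for r, rho, dec_on in itertools.product(rates, reductions, decrement_toggle):
        q = replace(
            p,
            discount_rate=r,
            le_reduction=rho,
            d_late=p.d_late if dec_on else 0.0,
        )
        res = evaluate(q, cost, gdp_per_capita)
        rows.append(
            {
                "discount_rate": r,
                "le_reduction": rho,
                "late_decrement_on": dec_on,
                "dalys_averted": res.dalys_averted,
                "cost_per_daly": res.cost_per_daly,
                "gdp_ratio": res.gdp_ratio,
                "classification": res.classification,
            }
        )
    return pd.DataFrame(rows)


class CalibrationError(RuntimeError):
    """No admissible (d_late, le_reduction) reproduces the observations."""


def calibrate_adjustments(
    cost: float,
    observed_ratios: Mapping[float, float],
    fixed: DalyParams,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Pin the unpublished adjustment parameters to printed cost/DALY values.

    Solves for ``(d_late, le_reduction)`` such that the model reproduces
    the observed cost-per-DALY values at each discount rate in
    ``observed_ratios`` (rate -> cost/DALY).  With two observations at
    distinct rates both parameters are identified; with a single
    observation only ``d_late`` is solved and ``le_reduction`` is held at
    its value in ``fixed``.

    Returns ``(d_late, le_reduction, residual)`` where residual is the
    max relative misfit over the observations.

    Raises
    ------
    CalibrationError
        If no root exists in [0, 1) x [0, 1), e.g. observations implying a
        negative decrement.
    """
    if not observed_ratios:
        raise CalibrationError("no observations supplied")
    targets = {r: cost / v for r, v in observed_ratios.items()}

    def averted_at(rate: float, d_late: float, rho: float) -> float:
        q = replace(fixed, discount_rate=rate, d_late=d_late, le_reduction=rho)
        return dalys_averted(q).dalys_averted

    eps = 1e-9
    if len(targets) == 1:
        ((rate, target),) = targets.items()
        rho = fixed.le_reduction
        f = lambda d: averted_at(rate, d, rho) - target
        if f(0.0) * f(1.0 - eps) > 0:
            raise CalibrationError(
                f"no d_late in [0,1) matches cost/DALY at rate {rate}: "
                f"f(0)={f(0.0):.4g}, f(1-)={f(1.0 - eps):.4g}"
            )
        d_late = optimize.brentq(f, 0.0, 1.0 - eps, xtol=1e-12)
    else:
        def residuals(x):
            d, rho = x
            return [averted_at(r, d, rho) - t for r, t in targets.items()]

        sol = optimize.least_squares(
            residuals,
            x0=[0.3, 0.1],
            bounds=([0.0, 0.0], [1.0 - eps, 1.0 - eps]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        d_late, rho = map(float, sol.x)

    rel = max(
        abs(averted_at(r, d_late, rho) - t) / t for r, t in targets.items()
    )
    # A pinned-at-bounds least-squares "solution" that misfits badly is a
    # failure, not a calibration.
    if rel > max(tol, 1e-3):
        raise CalibrationError(
            f"calibration residual {rel:.3g} exceeds tolerance; observations "
            "are inconsistent with d_late, le_reduction in [0, 1)"
        )
    return d_late, rho, rel
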