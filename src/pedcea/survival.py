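"""Kaplan-Meier estimation, log-rank tests and the cost-survival Cox model.

The product-limit estimator and its Greenwood confidence interval are
implemented here (the CI is computed on log S with normal quantiles and
truncated to [0, 1]); the log-rank test and the Cox proportional-hazards
fit delegate to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats as sps

__all__ = [
    "SurvivalSample",
    "km_curve",
    "km_estimate",
    "logrank",
    "cost_hazard_association",
]


class SurvivalDomainError(ValueError):
    """Invalid survival input."""


@dataclass
class SurvivalSample:
    """Right-censored survival data: per-patient time and event indicator."""

    times: np.ndarray
    events: np.ndarray  # True = death observed, False = censored

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.size == 0:
            raise SurvivalDomainError("empty survival sample")
        if self.times.size != self.events.size:
            raise SurvivalDomainError("times and events lengths differ")
        if np.any(self.times < 0):
            raise SurvivalDomainError("negative follow-up time")


def km_curve(sample: SurvivalSample, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit table: one row per distinct event time.

    Columns: time, at_risk, events, censored, survival, lower, upper.
    The CI is Greenwood's variance applied on the log-survival scale,
    truncated to [0, 1]; it has zero width before the first event.
    """
    t, e = sample.times, sample.events
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    z = sps.norm.ppf(1.0 - alpha / 2.0)

    rows = []
    surv = 1.0
    greenwood = 0.0  # sum d / (n (n - d))
    for ti in np.unique(t[e]):
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & e))
        c = int(np.sum((t == ti) & ~e))
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            greenwood += d / (at_risk * (at_risk - d))
            se_log = math.sqrt(greenwood)
            lo = surv * math.exp(-z * se_log)
            hi = surv * math.exp(z * se_log)
        else:  # survival hits zero; Greenwood variance degenerates
            lo, hi = 0.0, 0.0
        rows.append(
            {
                "time": float(ti),
                "at_risk": at_risk,
                "events": d,
                "censored": c,
                "survival": surv,
                "lower": max(0.0, min(lo, 1.0)),
                "upper": max(0.0, min(hi, 1.0)),
            }
        )
    return pd.DataFrame(
        rows, columns=["time", "at_risk", "events", "censored",
                       "survival", "lower", "upper"]
    )


def km_estimate(
    sample: SurvivalSample, t: float, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Kaplan-Meier survival probability at ``t`` with Greenwood 95% CI."""
    if t < 0:
        raise SurvivalDomainError(f"negative time {t}")
    curve = km_curve(sample, alpha=alpha)
    past = curve[curve["time"] <= t]
    if past.empty:
        return 1.0, 1.0, 1.0
    row = past.iloc[-1]
    return float(row["survival"]), float(row["lower"]), float(row["upper"])


def logrank(samples: Sequence[SurvivalSample]) -> tuple[float, float, int]:
    """Log-rank test across two or more strata.

    Returns ``(chi2, p_value, df)`` with df = number of strata - 1.
    """
    if len(samples) < 2:
        raise SurvivalDomainError("log-rank needs at least two strata")
    times = np.concatenate([s.times for s in samples])
    events = np.concatenate([s.events for s in samples])
    labels = np.concatenate(
        [np.full(s.times.size, i) for i, s in enumerate(samples)]
    )
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value), len(samples) - 1


def cost_hazard_association(
    df: pd.DataFrame,
    *,
    time_col: str = "followup_time",
    event_col: str = "event",
    cost_col: str = "cost_total",
    adjusters: Sequence[str] = (),
    strata: Sequence[str] = (),
    per: float = 1000.0,
    truncate_at: float | None = 5.0,
) -> dict:
    """Cox PH association between treatment cost and overall survival.

    The cost covariate is scaled to ``per`` currency units (hazard ratio
    per $1000 by default); follow-up is administratively censored at
    ``truncate_at`` years.  ``adjusters`` enter as regression covariates,
    ``strata`` as baseline-hazard strata.  Returns the hazard ratio with
    95% CI, the log-hazard coefficient and its SE, and a Schoenfeld
    proportional-hazards diagnostic p-value/flag.
    """
    work = df.copy()
    ev = work[event_col]
    if ev.dtype == object:
        ev = ev.eq("died")
    ev = ev.astype(bool)
    tt = work[time_col].astype(float)
    if truncate_at is not None:
        ev = ev & (tt <= truncate_at)
        tt = tt.clip(upper=truncate_at)
    if not ev.any():
        raise SurvivalDomainError("no events: Cox model not estimable")

    model = pd.DataFrame({"T": tt, "E": ev.astype(int)})
    model["cost_scaled"] = work[cost_col].astype(float) / per
    if float(model["cost_scaled"].std()) == 0.0:
        # no cost variation: the partial likelihood is flat at coef = 0
        return {
            "coef_per_unit": 0.0,
            "se": float("inf"),
            "hazard_ratio": 1.0,
            "hr_ci": (0.0, float("inf")),
            "ph_test_p": float("nan"),
            "ph_ok": True,
            "n_events": int(ev.sum()),
        }
    for col in adjusters:
        if pd.api.types.is_numeric_dtype(work[col]):
            model[col] = work[col].astype(float)
        else:
            model = model.join(
                pd.get_dummies(work[col], prefix=col, drop_first=True).astype(float)
            )
    strata_cols = list(strata)
    for col in strata_cols:
        model[col] = work[col]

    cph = CoxPHFitter()
    cph.fit(model, duration_col="T", event_col="E",
            strata=strata_cols or None)
    coef = float(cph.params_["cost_scaled"])
    se = float(cph.standard_errors_["cost_scaled"])
    z = sps.norm.ppf(0.975)
    try:
        ph = proportional_hazard_test(cph, model, time_transform="rank")
        ph_p = float(np.min(ph.summary["p"]))
    except Exception:  # degenerate designs (e.g. constant covariate)
        ph_p = float("nan")
    return {
        "coef_per_unit": coef,
        "se": se,
        "hazard_ratio": math.exp(coef),
        "hr_ci": (math.exp(coef - z * se), math.exp(coef + z * se)),
        "ph_test_p": ph_p,
        "ph_ok": not (ph_p == ph_p and ph_p < 0.05),
        "n_events": int(ev.sum()),
    }
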