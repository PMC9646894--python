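"""Currency conversion, inflation adjustment and cost summary statistics.

Costs are recorded in the currency and year they were incurred (EGP or
USD).  The adjustment convention is: convert at the incurrence year's
exchange rate, then inflate to the reference year with the GDP deflator
of the *target* currency's economy.  Real-terms local-currency analyses
(e.g. the 2013-vs-2017 comparison) never pass through USD.

Summary statistics are medians with seeded percentile-bootstrap 95%
confidence intervals; group comparisons use rank tests (Wilcoxon
rank-sum for two groups, Kruskal-Wallis for more).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "EconConfig",
    "DEFAULT_ECON",
    "adjust_cost",
    "median_ci",
    "compare_costs",
]


class EconLookupError(KeyError):
    """A year missing from an exchange-rate or deflator table."""


class CostDomainError(ValueError):
    """Invalid input to a cost summary operation."""


@dataclass(frozen=True)
class EconConfig:
    """Exchange rates, GDP deflators, reference year and GDP per capita.

    ``fx_table`` maps calendar year to EGP per USD; the deflator tables
    map year to a price index (any base — only ratios are used).
    """

    fx_table: Mapping[int, float]
    us_deflator: Mapping[int, float]
    egypt_deflator: Mapping[int, float]
    ref_year: int = 2019
    gdp_per_capita: float = 3019.0

    def __post_init__(self) -> None:
        for name, table in (
            ("fx_table", self.fx_table),
            ("us_deflator", self.us_deflator),
            ("egypt_deflator", self.egypt_deflator),
        ):
            if any(v <= 0 for v in table.values()):
                raise CostDomainError(f"{name} contains non-positive entries")
        for name in ("us_deflator", "egypt_deflator"):
            if self.ref_year not in getattr(self, name):
                raise CostDomainError(
                    f"reference year {self.ref_year} missing from {name}"
                )

    @classmethod
    def from_yaml(cls, path) -> "EconConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        for key in ("fx_table", "us_deflator", "egypt_deflator"):
            doc[key] = {int(y): float(v) for y, v in doc[key].items()}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {
            "fx_table": dict(self.fx_table),
            "us_deflator": dict(self.us_deflator),
            "egypt_deflator": dict(self.egypt_deflator),
            "ref_year": self.ref_year,
            "gdp_per_capita": self.gdp_per_capita,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh)


def _default_econ() -> EconConfig:
    # Approximate World Bank series (EGP per USD; GDP deflator indices,
    # 2019 = 100). Defaults for exploration — supply your own vintages
    # for any substantive analysis.
    fx = {
        2013: 6.87, 2014: 7.08, 2015: 7.69, 2016: 10.03,
        2017: 17.78, 2018: 17.77, 2019: 16.77, 2020: 15.76,
    }
    us = {
        2013: 91.0, 2014: 92.6, 2015: 93.5, 2016: 94.5,
        2017: 96.2, 2018: 98.4, 2019: 100.0, 2020: 101.3,
    }
    eg = {
        2013: 48.0, 2014: 53.0, 2015: 58.4, 2016: 64.9,
        2017: 81.0, 2018: 92.3, 2019: 100.0, 2020: 105.8,
    }
    return EconConfig(fx_table=fx, us_deflator=us, egypt_deflator=eg)


DEFAULT_ECON = _default_econ()


def _lookup(table: Mapping[int, float], year: int, name: str) -> float:
    try:
        return table[year]
    except KeyError:
        raise EconLookupError(f"year {year} missing from {name}") from None


def adjust_cost(
    amount: float,
    currency: str,
    year: int,
    target_currency: str,
    cfg: EconConfig = DEFAULT_ECON,
) -> float:
    """Express ``amount`` (incurred in ``currency`` in ``year``) in
    reference-year prices of ``target_currency``.

    Conversion uses the incurrence year's exchange rate; inflation uses
    the target economy's deflator ratio ref_year/year.
    """
    if currency not in ("EGP", "USD") or target_currency not in ("EGP", "USD"):
        raise CostDomainError(f"unknown currency {currency!r}/{target_currency!r}")
    value = amount
    if currency != target_currency:
        fx = _lookup(cfg.fx_table, year, "fx_table")
        value = value / fx if target_currency == "USD" else value * fx
    table_name = "us_deflator" if target_currency == "USD" else "egypt_deflator"
    table = getattr(cfg, table_name)
    value *= _lookup(table, cfg.ref_year, table_name) / _lookup(
        table, year, table_name
    )
    return value


def median_ci(
    values: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Median with a percentile-bootstrap confidence interval.

    Returns ``(median, lower, upper)``; reproducible under ``seed``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise CostDomainError(f"need >= 2 values for a median CI, got {arr.size}")
    if n_boot < 200:
        raise CostDomainError(f"n_boot={n_boot} < 200")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot_medians = np.median(arr[idx], axis=1)
    lo, hi = np.quantile(boot_medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    med = float(np.median(arr))
    return med, float(min(lo, med)), float(max(hi, med))


def compare_costs(groups: Sequence[Sequence[float]]):
    """Rank-based comparison of cost distributions.

    Two groups: Wilcoxon rank-sum (Mann-Whitney U, two-sided, asymptotic);
    more than two: Kruskal-Wallis.  Returns ``(statistic, p_value)``.
    """
    if len(groups) < 2:
        raise CostDomainError("need at least two groups to compare")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise CostDomainError("empty group in cost comparison")
    if len(arrays) == 2:
        res = stats.mannwhitneyu(
            arrays[0], arrays[1], alternative="two-sided", method="asymptotic"
        )
    else:
        res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)
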