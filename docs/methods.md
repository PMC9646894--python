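# Methods

## The DALYs-averted model

The core comparison is treatment versus no treatment for childhood
cancer, under the standard assumption that an untreated child does not
survive the disease. Effectiveness is the group's 5-year overall
survival `S`, read as a cure fraction: the model does not track
individual trajectories beyond the survivor/non-survivor split.

All life-year streams are discounted continuously, so a stream of
length `L` starting now is worth `D(L, r) = (1 − e^{−rL})/r`
year-equivalents (implemented with `expm1` so the `r → 0` limit is
exact). Continuous discounting was chosen over annual compounding
because it matches the convention of the DALY calculation models this
package follows and yields closed forms; at the rates used (0–6%) the
difference from annual compounding is well under 1%.

Per patient, with age at diagnosis `a`, life expectancy `LE`,
treatment duration `T`, treatment disability weight `dw_tx`, late-effect
utility decrement `d_late`, life-expectancy reduction `ρ`, and
non-survivor death time `δ`:

* **Untreated arm.** A child who would have been cured dies at
  diagnosis, losing `D(LE − a, r)`. A child who would have died anyway
  dies at `δ` — the same time as in the treated arm.
* **Treated arm, cured (probability S).** YLD during treatment
  `dw_tx · D(T, r)`; lifelong late-effect YLD
  `d_late · e^{−rT} · D((1−ρ)(LE−a) − T, r)`; YLL from excess late
  mortality `D(LE−a, r) − D((1−ρ)(LE−a), r)`.
* **Treated arm, non-survivor (probability 1−S).** Death at `δ`
  (`e^{−rδ} D(LE−a−δ, r)` YLL, identical to the untreated counterfactual
  and hence cancelling in the difference) plus treatment YLD
  `dw_tx · D(δ, r)`.

DALYs averted is the arm difference. Two consequences anchor the
construction: futile treatment (`S = 0`, `dw_tx = 0`) averts exactly
zero DALYs, and a perfect cure with no decrements averts the whole
untreated burden `D(LE − a, r)`. The matched-`δ` convention is what
guarantees the first property; attributing life-years between `δ` and
`LE` to a treatment that did not save the patient would overstate
effectiveness. The excess-late-mortality YLL term is what makes DALYs
averted strictly decreasing in `ρ`; without it a larger life-expectancy
reduction would paradoxically make treatment look *more*
cost-effective, because it would only shrink the window over which the
late-effect decrement accrues.

`dalys_no_treatment` exposes the untreated burden at diagnosis,
`D(LE − a, r)`, the familiar YLL quantity; the arm total stored in
`DalyResult.dalys_no_tx` additionally applies the matched-`δ`
convention to the non-survivor share so that
`dalys_averted = dalys_no_tx − dalys_tx` holds as an identity.

Uniform age weights are used throughout (no GBD-style `KCxe^{−βx}`
weighting); the cost-effectiveness literature this model follows reports
unweighted DALYs, and adding the machinery would change no result the
package reports.

### Parameters, units, defaults

| symbol | meaning | default | rationale |
|---|---|---|---|
| `LE` | life expectancy (years) | 72.06 | Egypt, 2020 vintage |
| `r` | discount rate (per year) | 0.03 | base case; 0.06 conservative sensitivity |
| `T` | treatment duration (years) | 2.0 | typical intensive-phase duration; assumption |
| `dw_tx` | disability weight under treatment | 0.20 | cancer-treatment-phase weights cluster near 0.2; assumption |
| `d_late` | lifelong late-effect utility decrement | 0.2836 | calibrated (below) |
| `ρ` | life-expectancy reduction | 0.1290 | calibrated (below) |
| `δ` | non-survivor death time (years) | 2.5 | midpoint of the 5-year OS window; assumption |
| GDP/capita | WHO-CHOICE denominator (USD) | 3019 | Egypt, 2019 |

The per-condition late-effect parameters used by the published DALY
spreadsheets are not printed in the sources this package emulates, so
`calibrate_adjustments` solves for `(d_late, ρ)` from observed
cost/DALY values: two observations at distinct discount rates identify
both parameters (bounded least squares in `[0,1)²`, residual reported,
failure raised when no admissible root exists); a single observation
identifies `d_late` with `ρ` held fixed (Brent root-finding). The
defaults above are the two-point calibration against the emulated
cohort's all-cancers pair ($1384/DALY at 3%, $2347/DALY at 6%) and
reproduce both to numerical precision. They are assumptions standing in
for unpublished appendix values, not estimates with uncertainty; any
per-group analysis that has better late-effect data should override
them. A consistency check backs their plausibility: calibrating
`d_late` on the 3% observation alone (with `ρ = 0`) predicts the 6%
value within about 3%.

### WHO-CHOICE classification

`ratio = cost/DALY ÷ GDP per capita`; `< 1` very cost-effective,
`1 ≤ ratio < 3` cost-effective, `≥ 3` not cost-effective. Boundary
values take the less favourable label — a deliberate tie-break, since
threshold statements of the form "<1×" and "between 1 and 3" leave the
boundary points ambiguous.

### Sensitivity analysis

`sensitivity_grid` crosses discount rates (default 0/3/6%) with
life-expectancy reductions (0/15/30%) and an on/off toggle for the
late-effect decrement; every cell is an independent model evaluation
(no shared state), so monotonicity properties of the model are directly
visible in the grid.

## Synthetic registry generator

The generator emulates the *statistical* structure of a five-year
accrual (2013–2017), three-further-years follow-up paediatric oncology
cohort of n = 8886:

* **Group mix** — 18 ICCC-3 diagnostic groups with the cohort shares,
  5-year OS and median 3-year USD-2019 costs of the emulated cohort's
  published per-group table; counts drawn multinomially.
* **Survival** — mixture cure: cured with probability `π`, else
  exponential death with rate `λ = ln2 / m` (non-cured median `m = 1.5`
  years, consistent with most cohort deaths occurring within three
  years of diagnosis). `π` solves `S(5) = π + (1−π)e^{−5λ}` exactly, so
  the model's true 5-year survival equals the configured target
  including the non-cured tail beyond five years; targets below the
  tail re-solve `λ` with `π = 0`.
* **Censoring** — administrative at `horizon − enrolment offset`, the
  offset uniform over the five accrual years (so censoring times span
  3–8 years at the default horizon of 8), plus independent
  loss-to-follow-up censoring at a rate giving 1.5% by three years.
* **Costs** — lognormal (default shape σ = 0.8, giving the right-skew
  and CI widths typical of 3-year oncology cost data) with a 1.8×
  multiplier for the relapsed/refractory/progressive share (default
  14.1%). The base log-mean is solved so the *mixture* median equals
  the configured group median; the multiplier itself is a configuration
  default, as the sources state only that relapsed disease costs more.
* **Demographics** — ages from the published five-bin mixture (uniform
  within bin), 58% male, diagnosis year tied to the enrolment offset.
  Per-group mean ages at diagnosis are not published; the cohort mean
  (6.4 y) is the default assumption for every group, and `GroupParams`
  exposes `mean_age` for users with better data.

What the generator does *not* emulate: per-patient cost composition
(personnel/drug/overhead shares), correlation between cost and survival
within a group (costs and death times are drawn independently given
relapse status), stage/risk-specific survival differences (`risk_stage`
is an independent label), and calendar-time trends in cost or survival.
Pipeline round-trip tests on synthetic data therefore validate the
estimators and plumbing — that configured survival and cost medians are
recovered, that stratified reports are internally consistent — not any
clinical claim about real registries. In particular the Cox
cost–survival association in a default synthetic cohort is null by
construction; parameter-recovery tests inject a known hazard ratio
instead.

## Survival statistics

Kaplan–Meier estimation is implemented directly (product-limit over
distinct event times) with Greenwood's variance applied on the log-S
scale, normal quantiles, truncated to [0, 1]; the interval has zero
width before the first event, and the estimator is cross-checked
against lifelines' point estimates in the tests. When the last at-risk
patient dies the estimate hits zero and the log-scale interval
degenerates to zero width there. The log-rank test and the Cox model
delegate to lifelines; the Cox fit scales cost to per-$1000 units,
supports categorical adjusters (dummy-coded) and baseline-hazard
strata, truncates follow-up at 5 years by administrative censoring, and
reports a scaled-Schoenfeld proportional-hazards p-value alongside the
hazard ratio. lifelines handles event-time ties with Efron's
approximation; all survival times generated or truncated in this
package are continuous, so ties do not arise in practice. A constant
cost covariate short-circuits to a unit hazard ratio (the partial
likelihood is flat).

## Costs engine

`adjust_cost` converts at the incurrence year's exchange rate and then
inflates by the target-economy deflator ratio. This ordering mirrors
the convention of converting local-currency costs with the World Bank
exchange rate and inflating in USD; the two orderings coincide exactly
when the exchange-rate path satisfies relative purchasing-power parity
with the two deflator paths (a property test). The shipped default
tables are approximate World Bank series for exploration; substantive
analyses must supply their own vintages via `EconConfig`
(YAML-loadable). Median CIs are percentile bootstrap with B = 2000 and
a seeded generator — chosen because the emulated analyses report median
costs with 95% CIs without naming a method, and the percentile
bootstrap is the assumption-light default for skewed cost data.

## ICER

The between-cohort ICER compares first and last accrual years on
3-year OS (the later cohort has only three years of follow-up) and
real-terms local-currency median costs, with cost-effectiveness-plane
quadrant labels when the sign pattern makes the ratio alone misleading.
Nominal-USD percent changes are reported separately from real-terms
local-currency changes; devaluation-adjusted USD bases are out of
scope.

## Problem sizes and numerical choices

Simulation-based tests use: n = 20,000 single-group cohorts for
survival/cost round-trips (tolerance 3 Monte-Carlo standard errors,
with the SE taken from the Greenwood interval or a bootstrap of the
median, so censoring is accounted for); 1000 null replicates for
log-rank and Kruskal–Wallis type-I-error checks (binomial MC envelope
around 0.05); n = 8000 for Cox parameter recovery at a true hazard
ratio of 1.025 per $1000 (within two standard errors). Discounted-year
integrals are verified against adaptive quadrature at 1e-6 relative
error. Root-finding tolerances: 1e-12 (Brent) and 1e-14 (least-squares
termination); calibration declares failure above a 1e-3 relative
residual.

## Known limitations

* The DALY model is cohort-level: it consumes group summaries (OS,
  median cost, mean age), not patient-level heterogeneity, so
  within-group cost–effect correlation never enters the ratio.
* `S` conflates 5-year survival with cure; late relapses beyond five
  years are absorbed into the late-mortality adjustment `ρ` rather than
  modelled.
* Calibrated `(d_late, ρ)` are jointly identified only up to the
  two observations used; different (e.g. per-condition) late-effect
  data would shift per-group results, though the classification verdicts
  are robust to substantial variation (see the sensitivity grid).
* Costs enter as point medians; no probabilistic sensitivity analysis
  (CEAC curves) is provided, matching the deterministic design of the
  analyses this package emulates.
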