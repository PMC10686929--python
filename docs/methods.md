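# Methods

## Design and estimand

The package implements a controlled pre/post (difference-in-differences
style) comparison on monthly routine-monitoring panels.  Health zones
are assigned to a program arm or a comparison arm within each province;
time is partitioned into five phases — a pre-program year (2016), a
baseline year (2017, the program's first calendar year), and three
program periods (2018-01..2020-12, 2021-01..2021-09, 2021-10..2022-03),
75 months in total.  The first two phases pool into the "before" window
and the last three into the "since" window; both windows are
configurable, and the defaults follow the evaluation design the package
reproduces.

For one indicator in one province, with four pooled phase means
(program/comparison × before/since):

* `double_difference = Δ_pro − Δ_non` where `Δ = Ind_since − Ind_before`
  per arm, in the indicator's native unit;
* `%impact = Δ_pro / Δ_non − 1`, a dimensionless fraction.

The ratio form expresses how much larger (or smaller, or
opposite-signed) the program arm's change was relative to the
comparison arm's.  Its identifying assumption is the usual parallel
one: absent the program, the program zones' change would have matched
the comparison zones' change, so shared secular trends and shared
shocks cancel.  No covariate adjustment, matching, weighting, standard
errors or significance testing are attempted: the estimand is a point
descriptive, and the simulation harness (below) is the package's
verification instrument.

Note the ratio is *not* the double difference rescaled: when the
comparison arm barely moves, %impact explodes while the double
difference stays small.  Both are always reported together.

## Phase means and pooling

A phase mean is the arithmetic mean of all *present* zone-month values
for the arm's zones over the window's months (complete-case averaging;
no imputation, matching the source design which describes none).  The
default pools every zone-month equally ("pooled"); a `zone_mean`
option averages within zones first.  The two coincide on balanced
panels and differ when zones contribute unequal month counts; the
pooled default reflects how monthly averages are computed from a flat
monitoring extract.

## Undefined and unstable ratios

* `|Δ_non| < denominator_epsilon` (default 1e-9, i.e. an exact zero up
  to float noise): %impact is UNDEFINED; the estimate carries the
  literal "undefined (unstable denominator)".
* `|Δ_non| < instability_threshold` (default 0.05): the value is
  returned but flagged `unstable_denominator`.  0.05 is half the
  printed resolution of the published tables, where rows with a
  comparison-arm change of 0.0 at one decimal nonetheless print finite
  impacts — proof that sub-resolution denominators occur and that such
  rows should be read with care.

## Interpretation (fold / literal) convention

With `p` the %impact rounded half-up to 2 decimals (the published
display precision; full precision is kept internally):

| case | fold | literal |
|---|---|---|
| p > 0 | p | "p times more" |
| p = 0 | 0 | "No change" |
| −1 < p < 0 | −(1 + p) | "&#124;fold&#124; times less" |
| p ≤ −1 | p | "&#124;p&#124; times less" |

For −1 < p < 0 both arms moved the same direction but the program arm
moved less; the printed magnitude is the attenuation ratio
`Δ_pro/Δ_non`, not `|p|`.  For p ≤ −1 the program arm moved against
the comparison arm and the magnitude printed is `|p|` itself.  The map
is deliberately discontinuous approaching zero from below (−0.02 reads
"0.98 times less" while 0 reads "No change"); it reproduces the
published convention exactly and users should be aware of it.

## Effect classification and polarity

Each indicator carries a polarity: HIGHER_BETTER (coverage,
consultations, admissions to treatment, cures, referrals to care) or
LOWER_BETTER (deaths, attrition, infections, dropout, edema, low birth
weight, malnutrition prevalence, mortality, hospital stay).  An
estimate is POSITIVE when the sign of the rounded %impact agrees with
the desired direction, NO_CHANGE at rounded zero (band configurable via
`no_change_tolerance`, default exact), NOT_POSITIVE otherwise, and
UNDEFINED when the ratio is.  Polarities live in the packaged registry
as data rows, reverse-engineered from which direction the published
tables list as a positive impact; bed occupancy is the one indicator
whose desired direction differs by province (higher utilization in
Kongo Central, relief of over-occupancy in Ituri) and uses a
per-province override.

## Aggregation

The published accounting is a dichotomy per domain × province:
POSITIVE counts as "with positive effect"; NO_CHANGE, NOT_POSITIVE and
UNDEFINED pool as "without effect", so the two counts sum to the
total (a finer three-way breakdown is also emitted).  Percentages are
half-up rounded to 1 decimal.  The cross-province "mean" column is the
*unweighted* mean of the two province percentages — 60.8 and 70.8
average to 65.8 — not the pooled proportion (65.5); the summary table
reports both conventions.

## Missing-data exclusion rule

An (indicator, province) pair is excluded when more than 2 calendar
years of its series are entirely missing — a year counts as missing
when no month of that year inside the study span has a present value in
either arm.  The rule is applied per province because the two
provincial registries differ.  "More than 2 years" is read as > 2
whole calendar years (the source systems report by calendar year); a
stricter month-count variant (> 24 missing span months) is available
via `month_rule=True`.  The filter is monotone: adding data never
excludes a previously retained pair.

## Synthetic panels and what they show

The generator emulates the study conditions: two provinces, 3
program / 28 comparison zones per province by default (the study's
program arms were 3 and 7 zones inside 31 and 36 zones), the 75-month
calendar, baseline levels and monthly trends at the scale of the
published monthly averages (levels ~1–10, trends ~0.02–0.05/month),
Gaussian (σ ≈ 0.1, clipped at zero) or Poisson noise, and 5%
completely-at-random missingness.

The comparison arm follows `μ + τ·t`; the program arm tracks it exactly
through the before window and gains an additive shift
`θ·τ·(t̄_since − t̄_before)` during the since window, which makes the
expected program-arm change `(1 + θ)` times the comparison arm's.  θ is
thus ground truth in the estimator's own units: noise-free runs return
it exactly, and `recovery_experiment` reports bias, spread,
UNDEFINED counts and classification accuracy over replicates.  Each
(zone, indicator) series has its own counter-based random stream
derived from the master seed, so enlarging the roster never perturbs
existing series and equal seeds give byte-identical output files.

What passing these tests does *not* show: real SNIS panels have
reporting shocks correlated across zones (COVID-19, conflict-driven
displacement), non-random missingness, and possible spillover between
arms — none of which the generator models.  The simulations verify the
*estimator*, not the design's causal assumptions on real data.

## Numerical choices

* Rounding is half away from zero via `decimal`, matching the published
  tables; float `round()` half-to-even would flip boundary cases.
* Identifiability requires τ ≠ 0 in simulation: with no secular trend
  the comparison arm does not change and the ratio is UNDEFINED — this
  is a property of the estimand, not a defect; such replicates are
  counted and reported.
* Gaussian values are clipped at zero to respect the non-negativity of
  monitoring values; with default levels (σ ≤ 0.1, μ ≥ 1) the clipping
  probability is negligible.
* Two published rows print only three phase means and one published
  impact value per province pair is irreproducible from its rounded
  printed means; the packaged fixture marks, row by row, what the
  printed inputs support checking (exact value, direction only,
  unstable denominator, or nothing) rather than guessing unpublished
  source data.

## Test-suite problem sizes

Replicated-recovery checks run 200 replicates of the 31-zone × 75-month
single-province panel for the main recovery assertion (mean within 3
empirical standard errors of the injected θ = 0.56) and 20–50
replicates for the secondary checks (trend cancellation, spread
monotonicity); the brute-force oracle comparison uses 100 random
4-zone × 6-month panels at 1e-12 agreement.  These sizes make the whole
suite run in well under a minute while leaving the Monte-Carlo
assertions with comfortable margins.

## Known limitations

* Point estimates only; no uncertainty quantification by design.
* The ratio statistic is unstable near Δ_non = 0; downstream users
  should respect the `unstable_denominator` flag rather than the bare
  number.
* The literal map's discontinuity at 0⁻ can read oddly for tiny
  negative impacts.
* Health-area (sub-zone) structure, population weights and covariates
  are out of scope.
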