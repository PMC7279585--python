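# Methods

## Model

The package decomposes the change in total deaths between a baseline and a
comparison population into contributions of three factors. A population's
demographic state is an `AgeSchedule` `(N, s, m)`: total size `N`
(persons), age-composition proportions `s` (summing to 1 over an ordered
age partition), and age-specific mortality rates `m` (deaths per person
per year). Total deaths `D = N Σᵢ sᵢ mᵢ` are multilinear in the three
factor blocks, so the finite difference `D₂ − D₁` expands *exactly* into
three main effects (`Mp`, `Ma`, `Mm`) and four interactions (`Ipa`,
`Ipm`, `Iam`, `Ipam`), every term anchored on baseline quantities (see
README for the formulas). The allocation

    A = Ma + ½Ipa + ½Iam + ⅓Ipam,  P = Mp + ½Ipa + ½Ipm + ⅓Ipam,
    M = Mm + ½Ipm + ½Iam + ⅓Ipam

is the Shapley value of each factor under the coalition function
"`D` with this subset of factors switched to comparison values". Two
consequences are asserted as tests rather than assumed: the allocation
equals the mean of the six sequential one-factor-at-a-time decompositions
(`ordering_oracle` recomputes this by brute force; agreement ≤ 1e-9
relative on 1000 random pairs), and swapping the two populations negates
`A`, `P`, `M` componentwise, so results do not depend on decomposition
order or on the choice of reference population.

Assumptions and conventions:

* The two schedules share an identical ordered age partition (any shared
  partition is accepted; the canonical one is twenty 5-year groups
  `<5 … 95+`).
* Counts are in persons throughout the core; I/O carries an optional
  `scale` factor (e.g. `1e6` for tables printed in millions) so units are
  converted exactly once, at ingest.
* Comparisons are always baseline → comparison, positive values meaning
  more deaths than baseline.
* Relative contributions ("attributed proportions") are
  `attributed deaths / baseline-year total deaths × 100`, signed. A
  non-positive denominator leaves them undefined (flagged, absolute values
  still returned).
* No uncertainty intervals are produced: the method is deterministic given
  the counts, and the input estimates carry no usable variances.

## Stratified pipeline

`decompose_series` fixes a baseline year (default 1990) and decomposes
every later year against it — a fixed-reference series, not year-over-year
chaining. Strata are (location, income category, sex, cause). Per-cause
decompositions use the cause-specific mortality schedule together with the
*all-cause* population size and age composition; size and composition are
properties of the population, not of a cause, and this convention makes
cause-level `A`/`P`/`M` sum exactly to the all-cause values (tested).
Proportions and rates are always recomputed from summed counts after any
aggregation, never averaged. Strata missing baseline rows are skipped with
a warning; a baseline year absent from the whole panel is a hard error.

Derived products:

* **Cause ranking** — causes ordered by ageing-attributed deaths `A`
  (summed over locations), top-k and bottom-k, ties broken by cause label;
  attributed proportions use the sex's all-cause baseline total as the
  denominator.
* **Location bins** — per sex and cause, the cause-specific attributed
  proportion of each location (again over the location's all-cause
  baseline deaths) is rounded to the nearest integer percent (half away
  from zero) and counted into bins 1–4, 5–9, 10–14, 15–19, ≥20; values
  below 1%, including negatives, are omitted. The rounding rule is a
  design choice: the bins are integer-labelled and contiguous, and
  round-half-up keeps the omitted `<1%` zone exactly `(−∞, 0.5)`.
* **Ratio R** — `M / A` per stratum where `A > 0`; strata with `A ≤ 0`
  are excluded (de-ageing populations have no meaningful "offset" ratio).
  Classes `R ≤ −1`, `−1 < R ≤ 0`, `R > 0` partition the included strata;
  the boundary `R = −1` (exact offset) belongs to the first class.
* Negative-`A` strata are reported everywhere except the ratio, where they
  are flagged excluded rather than dropped silently.

## Synthetic data generator

`generate_panel` emulates the *shape* of a multi-country mortality
extract: a complete crossing of location × sex × cause × year × age group
with population and death counts. Its dials map one-to-one onto the three
factors, so ground truth is known by construction:

* `growth_rate` (default 1.015/yr) — multiplicative growth of each
  location's total population; typical of late-20th-century national
  growth.
* `ageing_shift` (default 0.15 yr/yr) — target increment of the mean age
  of the composition per calendar year, comparable to the global drift
  observed over 1990–2017. Implemented as exponential tilting of a fixed
  baseline composition `s₀ ∝ exp(−0.03·age)`; the tilt is mapped from the
  requested increment by the first-order relation d(mean)/d(tilt) =
  Var(age), so the realised drift is approximate (within ~25% for default
  settings) while `ageing_shift = 0` leaves the composition exactly
  constant — which is what the exactness tests rely on.
* `mortality_trend` (default 0.985/yr) — multiplicative decline applied
  uniformly to all age-specific rates.
* `base_schedule` — a J-shaped baseline curve
  `a·exp(b·age) + c·exp(−age/d)` (Gompertz senescence plus a childhood
  component); defaults give ≈7/1000 under age 5, a minimum near age 10,
  and ≈0.3/yr at 95+.

Deaths are exact expectations `population × rate` by default, so
single-factor scenarios yield exactly one nonzero attributed component;
with `noise=True` rates get lognormal jitter (sd `noise_sd`, default 1%)
and deaths are Poisson draws clipped at the population. Locations differ
by deterministic size multipliers, sexes by deterministic rate multipliers,
causes split the all-cause rates by fixed weights; income categories are
assigned round-robin. The generator deliberately does **not** model
cohort dynamics, migration, or fertility: the decomposition consumes only
`(N, s, m)` per year, so mass-shifting the composition is sufficient for
every property the pipeline can exercise. Consequently, passing tests
demonstrate correctness of the decomposition and pipeline arithmetic on
realistic *shapes* of data, not calibration to any real country's levels,
nor the separation of ageing into fertility-decline versus
life-expectancy mechanisms (out of scope).

## Packaged published fixtures

`fixtures.py` embeds two small published summary tables: a global /
income-category population-and-deaths table (1990 and 2017, counts in
millions with percents, by sex and by three coarse age bands) and the
top/bottom-10 cause ranking by ageing-attributed deaths with attributed
proportions. Their printed counts are rounded (0.1 million, 1 thousand),
so consistency of percent cells is checked by interval arithmetic: the
printed percent ± half its ulp must overlap the percent range reachable
when every printed count moves by ± half of *its* ulp. For the ranking
table the naive recomputation is already within 0.05 of every printed
percent, so a direct 1-decimal comparison is used there. The age-band
rows double as a coarse three-band `StratumPanel` for worked examples;
decomposing it understates the ageing component relative to a 20-group
partition because within-band ageing is invisible — the README's worked
example says so explicitly.

## Numerical choices

* Composition vectors are renormalised exactly when `|Σs − 1| ≤ 1e-6` and
  rejected beyond that; proportions are always recomputed from counts at
  ingest, never trusted from input files.
* Zero-population age groups get rate 0 with a warning (the formulas need
  finite rates); zero population with nonzero deaths is an error.
* Additivity `A + P + M = ΔD` holds to ~1e-15 relative in practice; tests
  assert 1e-6, the oracle and antisymmetry checks 1e-9, relative to
  `max(D₁, D₂, 1)` so near-zero death changes do not inflate relative
  error.
* Display rounding is 1 decimal for percents; full precision is kept
  internally and in CSV output (12 significant digits, integral counts
  written as integers, fixed column order — byte-stable across runs).
* Problem sizes in tests and the acceptance script are kept small (2–8
  locations, 4–28 years, ≤1000 random schedule pairs); every property
  checked is scale-free, so these sizes already exercise the full code
  paths in seconds.

## Known limitations

* The ageing mechanism is compositional only; it cannot answer *why* a
  population aged.
* The mean-age control of the generator is first-order accurate; strong
  tilts over long horizons drift sublinearly.
* Interaction allocation is specific to three factors; the weights do not
  generalise as written to other factorisations.
* Ratio `R` is undefined (excluded) for `A ≤ 0`; comparisons of mortality
  change against ageing in de-ageing populations need a different
  statistic.
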