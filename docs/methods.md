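# Methods

## Model

`hemscost` prices one helicopter emergency medical service (HEMS) station
for one year.  The station flies four mission types — primary (emergency
scene) missions by day `x` and night `y`, secondary (interhospital transfer)
missions by day `z` and night `w` — each with an average billable duration
`b_x … b_w` in minutes and `t` take-offs per mission (default 2:
out-and-back).  Annual cost decomposes into

* **fixed cost** `a` (station infrastructure, aircraft depreciation,
  insurances) and **personnel cost** `p`, both independent of output;
* **jump-fixed maintenance**: airworthiness work is organised in service
  intervals.  A family of intervals `(threshold, price)` charges its price
  every time the annual activity passes a full multiple of the threshold, so
  the cost is `Σ_d floor(activity / threshold_d) · price_d` — piecewise
  constant, non-decreasing, jumping exactly at multiples.  Three families
  exist: take-off counts, engine minutes and winch usages;
* **variable cost**: medical material per mission (`i` = 120 € primary,
  `j` = 170 € secondary) and fuel `l` = 5.83 € per engine minute;
* an optional **special-equipment profile** (rescue winch or static rope): a
  share `α` of primary missions flies with the equipment, with `m`-corrected
  starts and `n`-corrected duration, plus `r` training starts of `s` minutes
  and additional yearly personnel/fixed costs `o` and `v`.  With `α = 0` the
  profile is inert — no cost term sees it, including training flights.

The **average cost of one daytime primary mission** allocates the
output-independent blocks with an area key: the primary remit serves
`β` = 11,550 km², the secondary remit `γ` = 23,000 km², so the primary
remit carries the share `β/(β+γ)` of `a` and of the daytime personnel cost
`p·q`.  The primary fixed-cost slice is spread over billable primary minutes
`x·b_x + y·b_y`; start- and flight-time maintenance is spread over all
engine minutes and the share of training-plus-primary minutes folded back
per mission; special-equipment and winch costs are spread over the
`CEIL(α·x)` equipped missions and re-weighted by `α`.  The variable
component is the constant marginal cost `l·b_x·((1−α)+α·n) + i`.

**Break-even**: revenue is `P ·` billable minutes (training minutes earn
nothing; default tariff `P` = 70 €/min, configurable — e.g. 43.94 €/min for
the German civil-protection fleet).  Profit is affine in `x` between
maintenance jumps and drops by the triggered interval price at each jump, so
a crossing into profit can be transient.  The scan therefore reports the
*sustainable* break-even — the smallest `x` whose profit stays nonnegative
for every larger `x` in the scanned range — next to any transient crossings.

## Scenario fixtures

The fifteen built-in parameter sets (`data/scenarios.yaml`) are the study
conditions of the underlying cost analysis of a German rural HEMS station:
scenarios 1/2/3 with 12/16/24 daily operating hours (night missions
`y` = 120, `w` = 140 only in the 24-h scenario; `q` = 4/7 daytime personnel
share there, 5/9 in its static-rope variation) crossed with variations
I initial, II high-cost (larger `a`, `p` and maintenance prices), III
dual-use (`z` = 400 secondary missions), IV static rope
(`α` = 0.05, `m` = 1.5, `n` = 2, 300 × 20 min training) and V rescue winch
(`α` = 0.1, `m` = 0.5, `n` = 2, 100 × 60 min training, winch intervals
1 usage → 100 €, 20 usages → 3,000 €).  They are data, not code: the free
variable of every sweep is `x`.

`scenario_engine.perturbed_variation` jitters costs, thresholds and mission
counts multiplicatively (default ±30 %) while preserving all type
invariants; property tests use it to exercise the model away from the
fixtures.  The fixtures emulate a planning calculation, not field data: all
durations and consumptions are annual averages, mission counts are
deterministic, and no seasonality, weather aborts, parallel-dispatch
conflicts or price inflation are represented.  Passing tests therefore
validate the cost arithmetic and its published calibration, not the
operational variability of a real station.

## Numerical conventions

* **floor/CEIL.** `floor` in the maintenance terms and `CEIL` in the
  special-equipment terms are the standard integer operators;
  `CEIL(integer) = integer` (e.g. `CEIL(0.1·1200) = 120`).  Both are
  evaluated with a 1e-9 guard so that activities that are exact threshold
  multiples up to float round-off (`0.05·900·…`) land on the intended side.
* **Flight-time thresholds are engine minutes** (3,000 / 6,000 / 18,000 /
  36,000), although interval ladders of this size are colloquially quoted in
  hours; only the minute reading reproduces the published maintenance cells.
* **Rounding.** All arithmetic runs at full float precision; currency is
  rounded half-up to 2 decimals only at presentation/serialisation
  (`round_currency`).  CSV output uses a plain `.` decimal separator;
  German-formatted amounts (`1.697.546,20`, `43,94`) are accepted on input
  and normalised.
* **Interval ladders** are normalised to ascending threshold order on
  construction (thresholds must be distinct), which makes the cost functions
  invariant under permutation of the configured lists.
* **Degenerate inputs.** `x = 0` is rejected for per-mission averages
  (undefined); an active special profile with no winch intervals is legal
  (winch cost 0, as in the static-rope variation); an empty year costs
  exactly `a + p + o + v`.

## Open design choices and how they were resolved

The published scenario tables are not fully derivable from the printed cost
functions under one consistent reading.  Where two readings circulate, both
are implemented and the choice is an explicit mode:

* **Secondary material** (`secondary_material_mode`): the cost function
  values secondary missions at `j` (= `formula`, the default, and the
  reading behind the headline total 1,697,546.20 €); the published table
  totals value them at `i` (= `table`).  The two differ by `(j−i)·(z+w)`.
* **Fixed-cost denominator** (`fixed_denominator`): the average-cost
  function spreads the fixed slice over primary minutes
  (`primary_minutes`, default); the published dual-use (variation III)
  cells use daytime minutes `x·b_x + z·b_z` (`daytime_minutes`).
* **Daytime personnel** (`daytime_personnel_cost`): the published 24-h
  cells use the corresponding 12-h scenario's personnel sum instead of
  `p·q`; the override reproduces them without changing the fixtures.
* **Fuel on training flights**: the equipment footnotes state that training
  flights consume fuel, so fuel is charged on *all* engine minutes,
  training included.  (All externally validated quantities have `α = 0`,
  where the readings coincide.)
* **Winch maintenance** follows the same summed interval-ladder operator as
  the other families, although the printed total-cost function shows a
  single winch term.

`hemscost validate` recomputes all 315 published table cells.  Cells that no
documented reading reproduces are classified as *known deviations* and
reported with the formula-faithful value: the special-equipment (IV/V)
average-maintenance cells, the variation III/IV/V total-cost columns (the
III totals omit the variable cost of the additional secondary missions),
and the `avg_total`/`primary_total` cells that inherit a deviating
component.  The published break-even counts are likewise only partly
recoverable: the scan reproduces 800 missions for the initial 12-h scenario
under the `table` material convention (804 under `formula`); the other
published counts (728, 959, 1020) are near but not equal to the scanned
values, and the scan results are reported as computed.

## Problem sizes and defaults

Tables evaluate `x ∈ {900, 1200, 1500}` by default; curves and break-even
scans run per integer mission over `x ∈ [1, 2000]`, which covers the full
utilisation range of a German primary-transport helicopter (≈1,400 missions
per year at high occupancy) with margin.  A full 15-fixture sweep over that
range takes well under a minute on one CPU; every quantity is exact
arithmetic, so there is no convergence or tolerance tuning anywhere in the
model itself.

## Limitations

The model is an annual, deterministic planning calculation: it cannot say
anything about within-year cash flow, stochastic demand, queueing or
coverage of HEMS networks, and it deliberately excludes cost-effectiveness
or benefit analysis, currency conversion and discounting of capital costs.
Calibration rests on a single operator's disclosed figures; the documented
table inconsistencies mean that a handful of published cells cannot serve
as validation anchors and are tracked as deviations instead.
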