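# hemscost

Full-cost simulation of a helicopter emergency medical service (HEMS)
station: deterministic annual cost with jump-fixed maintenance intervals,
average cost per primary rescue mission under an area-based allocation key,
and break-even analysis against a per-engine-minute tariff.

The package is aimed at health economists and EMS planners who need to
understand the cost dynamics of air rescue — how average mission costs fall
with utilisation (fixed-cost digression), how maintenance intervals break
that decline with sudden jumps, and at what mission volume a station covers
its costs under a given reimbursement tariff.

## The model

Total annual cost of one station is

```
K = a + p + o + v
    + Σ_d floor( (r + (1−α)·t·x + α·x·t·m + t·(y+z+w)) / u_d ) · c_d      (start-dependent maintenance)
    + Σ_d floor( (r·s + (1−α)·x·b_x + α·b_x·x·n + y·b_y + z·b_z + w·b_w) / e_d ) · f_d   (flight-time maintenance)
    + Σ_d floor( (α·x + r) / g_d ) · h_d                                  (winch maintenance)
    + i·(x+y) + j·(z+w)                                                   (medical material)
    + l · (all engine minutes)                                            (fuel)
```

where `x, y` are primary missions by day/night, `z, w` secondary
(interhospital) missions, `b_*` billable durations in minutes, `t` starts per
mission, and `α, m, n, r, s, o, v` describe an optional special-equipment
(winch / static rope) profile.  Maintenance is *jump-fixed*: each family of
service intervals `(threshold u_d, price c_d)` charges its price at every
full multiple of accumulated starts, engine minutes or winch usages.
Flight-time thresholds are engine **minutes**.

The average cost `k` of one daytime primary mission distributes fixed and
personnel costs between the primary and secondary remit with the area key
`β/(β+γ)` (operating areas in km²), spreads the primary slice over billable
primary minutes, allocates start/flight-time maintenance by the primary
share of engine minutes, and adds the constant marginal cost
`l·b_x·((1−α)+α·n) + i`.  Break-even compares `K` with revenue
`P · billable minutes` (training flights are not billable) and reports the
smallest mission count whose profit never falls back below zero — a
maintenance jump can make an earlier crossing merely transient.

Fifteen built-in scenario variations (12/16/24 daily operating hours ×
{initial, high-cost, dual-use, static-rope, winch} assumptions) ship as a
YAML fixture file and drive all tables, curves and scans.

## Worked example

```
$ hemscost tables --scenario 1.I --x 900,1200,1500 --material-mode table
scenario,x,y,z,w,avg_fixed,avg_personnel,avg_maintenance,avg_variable,avg_total,primary_total,total
1.I,900,0,92,0,117.54,268.92,135.32,236.60,758.39,682549.10,1438366.20
1.I,1200,0,92,0,88.16,201.69,236.96,236.60,763.41,916090.16,1692946.20
1.I,1500,0,92,0,70.53,161.35,210.31,236.60,678.79,1018186.21,1789526.20
```

Each row prices one year of the initial 12-hour scenario at `x` primary and
92 secondary missions: the average primary mission costs 758.39 € at 900
missions and 678.79 € at 1500 — the fixed-cost digression — but 763.41 € at
1200, because between 900 and 1200 missions the start counter crosses the
2400-start overhaul threshold and maintenance jumps.  `primary_total` is the
yearly cost allocated to the primary remit, `total` the full annual cost of
the station.

```
$ hemscost breakeven --scenario 1.I --price 70 --x-max 1500 --material-mode table -o profit.csv
1.I: sustainable break-even at x = 800 (tariff 70.00 €/min)
```

At a tariff of 70 € per billable minute the station covers its costs from
the 800th primary mission onward (804 when secondary material is valued at
its own rate `j`; see `--material-mode`).

Other entry points: `hemscost curve` writes the per-mission average-cost
curve with flagged maintenance jumps, `hemscost validate` recomputes every
published scenario-table cell and classifies the handful of documented
deviations, and everything is available as a library
(`hemscost.total_cost`, `hemscost.average_primary_cost`,
`hemscost.break_even`, ...).

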