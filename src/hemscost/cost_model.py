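"""Cost functions for a helicopter emergency medical service (HEMS) station.

The model prices one rescue helicopter for a full year of operations. Annual
cost is the sum of

* fixed costs ``a`` (station, aircraft depreciation, insurances, ...),
* personnel costs ``p`` (crew, administration, airworthiness checks),
* special-equipment add-ons ``o`` (personnel) and ``v`` (fixed) when a winch
  or static rope is carried,
* jump-fixed maintenance: every maintenance family (take-off counter, engine
  minutes, winch usages) has a ladder of service intervals; each interval
  charges its price every time the annual activity crosses a multiple of its
  threshold,
* variable costs: medical material per mission (``i`` primary, ``j``
  secondary) and fuel ``l`` per engine minute.

The average cost of one *primary* mission allocates fixed and personnel cost
between the primary and secondary remits with an area key ``beta/(beta+gamma)``
(operating areas in km^2), spreads maintenance over the engine minutes flown
for the primary remit, and adds the constant marginal cost of one mission.

All arithmetic is plain float at full precision; currency is rounded only for
presentation (see :func:`round_currency`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

__all__ = [
    "MissionProfile",
    "MaintenanceSchedule",
    "SpecialEquipmentProfile",
    "CostParameters",
    "CostBreakdown",
    "AverageCostBreakdown",
    "EngineMinutes",
    "step_cost",
    "total_starts",
    "total_engine_minutes",
    "winch_usages",
    "total_cost",
    "average_primary_cost",
    "primary_mission_total_cost",
    "round_currency",
]

#: Tolerance used when an activity level lands on an interval threshold up to
#: float noise (e.g. 0.05 * 1200 * 2 * 20 accumulating to 2399.9999999999995).
_FLOAT_TOL = 1e-9

SECONDARY_MATERIAL_MODES = ("formula", "table")
FIXED_DENOMINATOR_MODES = ("primary_minutes", "daytime_minutes")


def round_currency(value: float) -> float:
    """Round a euro amount half-up to 2 decimals (presentation only)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _floor_units(amount: float, threshold: float) -> int:
    """``floor(amount / threshold)`` robust to float noise at exact multiples."""
    return int(math.floor(amount / threshold + _FLOAT_TOL))


def _ceil_units(value: float) -> int:
    """Least integer >= value; an exact integer maps to itself (CEIL(60)=60)."""
    nearest = round(value)
    if abs(value - nearest) <= _FLOAT_TOL:
        return int(nearest)
    return int(math.ceil(value))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissionProfile:
    """Annual mission counts and average billable durations.

    Parameters
    ----------
    x, y
        Primary missions flown at daytime / nighttime (count per year).
    z, w
        Secondary (interhospital transfer) missions at daytime / nighttime.
    b_x, b_y, b_z, b_w
        Average billable duration of the four mission types, minutes.
    """

    x: int
    y: int = 0
    z: int = 0
    w: int = 0
    b_x: float = 20.0
    b_y: float = 20.0
    b_z: float = 45.0
    b_w: float = 45.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "w"):
            count = getattr(self, name)
            if not isinstance(count, int) or isinstance(count, bool):
                raise TypeError(f"mission count {name!r} must be an integer, got {count!r}")
            if count < 0:
                raise ValueError(f"mission count {name!r} must be >= 0, got {count}")
        for name in ("b_x", "b_y", "b_z", "b_w"):
            duration = getattr(self, name)
            if not duration > 0:
                raise ValueError(f"billable duration {name!r} must be > 0, got {duration}")

    def with_x(self, x: int) -> "MissionProfile":
        """Copy of the profile with the free variable (daytime primaries) set."""
        return replace(self, x=x)


@dataclass(frozen=True)
class MaintenanceSchedule:
    """Jump-fixed maintenance interval ladders.

    Each family is a list of ``(threshold, price)`` pairs: every full multiple
    of ``threshold`` units of activity accumulated over the year triggers one
    service at ``price`` euro.  Intervals are normalized to ascending
    threshold order on construction; thresholds must be distinct and positive.

    Families: ``start_intervals`` count take-offs, ``flighttime_intervals``
    count engine minutes, ``winch_intervals`` count winch deployments (empty
    for aircraft without a hoist).
    """

    start_intervals: tuple[tuple[float, float], ...] = ()
    flighttime_intervals: tuple[tuple[float, float], ...] = ()
    winch_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        limits = {"start_intervals": 4, "flighttime_intervals": 4, "winch_intervals": 2}
        for name, max_len in limits.items():
            intervals = tuple(sorted((float(t), float(c)) for t, c in getattr(self, name)))
            if len(intervals) > max_len:
                raise ValueError(f"{name} supports at most {max_len} intervals, got {len(intervals)}")
            thresholds = [t for t, _ in intervals]
            if any(t <= 0 for t in thresholds):
                raise ValueError(f"{name} thresholds must be strictly positive")
            if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
                raise ValueError(f"{name} thresholds must be strictly increasing (distinct)")
            if any(c < 0 for _, c in intervals):
                raise ValueError(f"{name} prices must be >= 0")
            object.__setattr__(self, name, intervals)


@dataclass(frozen=True)
class SpecialEquipmentProfile:
    """Winch / static-rope add-on to the standard primary-mission profile.

    ``alpha`` is the share of primary missions flown with the equipment.
    Special missions take ``m`` times the usual starts and ``n`` times the
    usual billable duration; the crew additionally flies ``r`` training starts
    of ``s`` minutes per year, and the equipment adds ``o`` (personnel) and
    ``v`` (fixed) euro of yearly cost.  With ``alpha == 0`` the profile is
    inert: no term of any cost function sees it.
    """

    alpha: float = 0.0
    m: float = 1.0
    n: float = 1.0
    r: int = 0
    s: float = 0.0
    o: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.alpha > 0 and (self.m <= 0 or self.n <= 0):
            raise ValueError("correction factors m and n must be > 0 when alpha > 0")
        if self.r < 0 or self.s < 0 or self.o < 0 or self.v < 0:
            raise ValueError("r, s, o, v must be >= 0")

    @property
    def active(self) -> bool:
        return self.alpha > 0.0


@dataclass(frozen=True)
class CostParameters:
    """Every parameter of the annual cost function.

    Parameters
    ----------
    a
        Yearly fixed cost for standard operations, euro.
    p
        Yearly personnel cost, euro.
    q
        Share of personnel cost attributable to daytime operations, (0, 1].
    i, j
        Valued average medical-material consumption per primary / secondary
        mission, euro.
    l
        Valued average fuel consumption per engine minute, euro/min.
    t
        Take-offs per mission (a mission is normally out-and-back: t = 2).
    beta, gamma
        Operating areas of the primary / secondary remit, km^2; they define
        the allocation key beta/(beta+gamma).
    schedule, special
        Maintenance ladders and special-equipment add-on.
    price_per_minute
        Revenue tariff P per billable flight minute, euro (break-even only).
    """

    a: float
    p: float
    q: float = 1.0
    i: float = 120.0
    j: float = 170.0
    l: float = 5.83
    t: int = 2
    beta: float = 11550.0
    gamma: float = 23000.0
    schedule: MaintenanceSchedule = field(default_factory=MaintenanceSchedule)
    special: SpecialEquipmentProfile = field(default_factory=SpecialEquipmentProfile)
    price_per_minute: float = 70.0

    def __post_init__(self) -> None:
        if min(self.a, self.p, self.i, self.j, self.l) < 0:
            raise ValueError("a, p, i, j, l must be >= 0")
        if self.t < 1:
            raise ValueError(f"starts per mission t must be >= 1, got {self.t}")
        if not (self.beta > 0 and self.gamma > 0):
            raise ValueError("operating areas beta and gamma must be > 0")
        if not 0 < self.q <= 1:
            raise ValueError(f"daytime personnel share q must lie in (0, 1], got {self.q}")
        if self.price_per_minute < 0:
            raise ValueError("price_per_minute must be >= 0")

    @property
    def primary_share(self) -> float:
        """Area allocation key for the primary remit, beta/(beta+gamma)."""
        return self.beta / (self.beta + self.gamma)

    @property
    def secondary_share(self) -> float:
        """Complementary key gamma/(beta+gamma); the two sum to one."""
        return self.gamma / (self.beta + self.gamma)


@dataclass(frozen=True)
class CostBreakdown:
    """Total annual cost split into its additive components (euro)."""

    fixed: float
    personnel: float
    special_personnel: float
    special_fixed: float
    maintenance_starts: float
    maintenance_flighttime: float
    maintenance_winch: float
    material: float
    fuel: float

    @property
    def maintenance(self) -> float:
        return self.maintenance_starts + self.maintenance_flighttime + self.maintenance_winch

    @property
    def total(self) -> float:
        return (
            self.fixed
            + self.personnel
            + self.special_personnel
            + self.special_fixed
            + self.maintenance_starts
            + self.maintenance_flighttime
            + self.maintenance_winch
            + self.material
            + self.fuel
        )


@dataclass(frozen=True)
class AverageCostBreakdown:
    """Per-primary-mission averages, column for column as in the cost tables."""

    avg_fixed: float
    avg_personnel: float
    avg_maintenance: float
    avg_variable: float

    @property
    def avg_total(self) -> float:
        return self.avg_fixed + self.avg_personnel + self.avg_maintenance + self.avg_variable


@dataclass(frozen=True)
class EngineMinutes:
    """Annual engine runtime split by purpose (minutes)."""

    training: float
    primary: float
    other: float

    @property
    def total(self) -> float:
        return self.training + self.primary + self.other


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def step_cost(amount: float, intervals: Sequence[tuple[float, float]]) -> float:
    """Jump-fixed cost of an activity level against an interval ladder.

    Returns ``sum_d floor(amount / threshold_d) * price_d``: piecewise
    constant, non-decreasing, jumping exactly at integer multiples of each
    threshold.  ``amount`` is the activity accumulated over the year (starts,
    engine minutes or winch usages) and may be fractional.
    """
    if amount < 0:
        raise ValueError(f"activity amount must be >= 0, got {amount}")
    ladder = sorted((float(t), float(c)) for t, c in intervals)
    thresholds = [t for t, _ in ladder]
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be strictly positive")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return float(sum(_floor_units(amount, t) * c for t, c in ladder))


def total_starts(params: CostParameters, profile: MissionProfile) -> float:
    """Annual take-offs feeding the start-dependent maintenance counter.

    ``r + (1-alpha)*t*x + alpha*x*t*m + t*(y+z+w)``; special-mission starts
    are corrected by ``m`` and training starts ``r`` only count while special
    equipment is operated.
    """
    sp = params.special
    t = params.t
    starts = float(t * (profile.y + profile.z + profile.w))
    if sp.active:
        starts += sp.r + (1.0 - sp.alpha) * t * profile.x + sp.alpha * profile.x * t * sp.m
    else:
        starts += float(t * profile.x)
    return starts


def total_engine_minutes(params: CostParameters, profile: MissionProfile) -> EngineMinutes:
    """Annual engine minutes, split into training / primary / other flying.

    ``r*s + (1-alpha)*x*b_x + alpha*b_x*x*n + y*b_y + z*b_z + w*b_w``; winch
    or rope missions run ``n`` times the standard primary duration.
    """
    sp = params.special
    other = profile.y * profile.b_y + profile.z * profile.b_z + profile.w * profile.b_w
    if sp.active:
        training = float(sp.r * sp.s)
        primary = (1.0 - sp.alpha) * profile.x * profile.b_x + sp.alpha * profile.b_x * profile.x * sp.n
    else:
        training = 0.0
        primary = float(profile.x * profile.b_x)
    return EngineMinutes(training=training, primary=primary, other=float(other))


def winch_usages(params: CostParameters, profile: MissionProfile) -> float:
    """Annual winch deployments ``alpha*x + r`` (0 without special equipment)."""
    sp = params.special
    if not sp.active:
        return 0.0
    return sp.alpha * profile.x + sp.r


def total_cost(
    params: CostParameters,
    profile: MissionProfile,
    *,
    secondary_material_mode: str = "formula",
) -> CostBreakdown:
    """Total annual cost of the station, by component.

    ``secondary_material_mode`` selects how medical material of secondary
    missions is valued: ``"formula"`` uses the secondary rate ``j`` (the cost
    function as written), ``"table"`` values it at the primary rate ``i``
    (the convention behind the published scenario-table totals).
    """
    if secondary_material_mode not in SECONDARY_MATERIAL_MODES:
        raise ValueError(
            f"secondary_material_mode must be one of {SECONDARY_MATERIAL_MODES}, "
            f"got {secondary_material_mode!r}"
        )
    sp = params.special
    minutes = total_engine_minutes(params, profile)
    j_eff = params.j if secondary_material_mode == "formula" else params.i
    return CostBreakdown(
        fixed=float(params.a),
        personnel=float(params.p),
        special_personnel=float(sp.o) if sp.active else 0.0,
        special_fixed=float(sp.v) if sp.active else 0.0,
        maintenance_starts=step_cost(total_starts(params, profile), params.schedule.start_intervals),
        maintenance_flighttime=step_cost(minutes.total, params.schedule.flighttime_intervals),
        maintenance_winch=step_cost(winch_usages(params, profile), params.schedule.winch_intervals),
        material=params.i * (profile.x + profile.y) + j_eff * (profile.z + profile.w),
        # fuel is burnt in every engine minute, training flights included
        fuel=params.l * minutes.total,
    )


def _personnel_numerator(params: CostParameters, daytime_personnel_cost: Optional[float]) -> float:
    if daytime_personnel_cost is not None:
        if daytime_personnel_cost < 0:
            raise ValueError("daytime_personnel_cost override must be >= 0")
        return float(daytime_personnel_cost)
    return params.p * params.q


def _fixed_denominator(profile: MissionProfile, mode: str) -> float:
    if mode == "primary_minutes":
        return profile.x * profile.b_x + profile.y * profile.b_y
    if mode == "daytime_minutes":
        return profile.x * profile.b_x + profile.z * profile.b_z
    raise ValueError(f"fixed_denominator must be one of {FIXED_DENOMINATOR_MODES}, got {mode!r}")


def average_primary_cost(
    params: CostParameters,
    profile: MissionProfile,
    *,
    fixed_denominator: str = "primary_minutes",
    daytime_personnel_cost: Optional[float] = None,
) -> AverageCostBreakdown:
    """Average cost of one daytime primary mission.

    Fixed and personnel costs enter through the area key beta/(beta+gamma);
    the primary-remit slice of the fixed cost is spread over billable primary
    minutes (``fixed_denominator="primary_minutes"``, the function as
    written) or over billable daytime minutes (``"daytime_minutes"``, the
    convention behind the published dual-use table cells).  Start- and
    flight-time maintenance is allocated by the primary share of engine
    minutes (training included); special-equipment and winch costs are spread
    over the CEIL(alpha*x) equipped missions and folded back with weight
    alpha.  Variable cost is the constant marginal cost of one mission.

    ``daytime_personnel_cost`` optionally replaces the numerator ``p*q``
    (used to replicate published 24-h-scenario cells).

    Raises ``ValueError`` for ``x == 0`` (the average is undefined).
    """
    if profile.x < 1:
        raise ValueError("average cost per primary mission requires x >= 1")
    sp = params.special
    share = params.primary_share
    x = profile.x

    avg_fixed = params.a * share / _fixed_denominator(profile, fixed_denominator) * profile.b_x
    if sp.active:
        avg_fixed += (sp.o + sp.v) / _ceil_units(sp.alpha * x) * sp.alpha

    avg_personnel = _personnel_numerator(params, daytime_personnel_cost) * share / x

    minutes = total_engine_minutes(params, profile)
    wear = step_cost(total_starts(params, profile), params.schedule.start_intervals) + step_cost(
        minutes.total, params.schedule.flighttime_intervals
    )
    avg_maintenance = wear / minutes.total * (minutes.training + minutes.primary) / x
    if sp.active:
        winch = step_cost(winch_usages(params, profile), params.schedule.winch_intervals)
        avg_maintenance += winch / _ceil_units(sp.alpha * x) * sp.alpha

    avg_variable = params.l * ((1.0 - sp.alpha) * profile.b_x + sp.alpha * profile.b_x * sp.n) + params.i

    return AverageCostBreakdown(
        avg_fixed=avg_fixed,
        avg_personnel=avg_personnel,
        avg_maintenance=avg_maintenance,
        avg_variable=avg_variable,
    )


def primary_mission_total_cost(
    params: CostParameters,
    profile: MissionProfile,
    *,
    fixed_denominator: str = "primary_minutes",
    daytime_personnel_cost: Optional[float] = None,
) -> float:
    """Annual cost allocated to the primary-mission remit, euro.

    Area-key slices of fixed and personnel cost, the primary-minute share of
    start/flight-time maintenance, the special-equipment and winch costs
    attributable to the equipped missions, plus the variable cost of all
    primary missions.  Reconciles with ``x * avg_total`` by construction of
    the allocation (the two are computed independently).
    """
    if profile.x < 1:
        raise ValueError("primary-mission total cost requires x >= 1")
    sp = params.special
    share = params.primary_share
    x = profile.x

    fixed_alloc = params.a * share * (x * profile.b_x) / _fixed_denominator(profile, fixed_denominator)
    personnel_alloc = _personnel_numerator(params, daytime_personnel_cost) * share

    minutes = total_engine_minutes(params, profile)
    wear = step_cost(total_starts(params, profile), params.schedule.start_intervals) + step_cost(
        minutes.total, params.schedule.flighttime_intervals
    )
    maintenance_alloc = wear * (minutes.training + minutes.primary) / minutes.total

    special_alloc = 0.0
    if sp.active:
        equipped = sp.alpha * x / _ceil_units(sp.alpha * x)
        winch = step_cost(winch_usages(params, profile), params.schedule.winch_intervals)
        special_alloc = (sp.o + sp.v + winch) * equipped

    variable_alloc = (
        params.l * ((1.0 - sp.alpha) * profile.b_x + sp.alpha * profile.b_x * sp.n) + params.i
    ) * x

    return fixed_alloc + personnel_alloc + maintenance_alloc + special_alloc + variable_alloc
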