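"""Scenario fixtures, parameter sweeps and table/curve reproduction.

Fifteen built-in scenario variations describe a single-helicopter HEMS
station under 12/16/24 daily operating hours (scenarios 1-3) crossed with
five cost assumptions (variations I-V: initial, high cost, dual-use, static
rope, rescue winch).  They are shipped as a YAML data file whose values are
the study conditions; the number of daytime primary missions ``x`` is the
free variable of every sweep.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd
import yaml

from .cost_model import (
    AverageCostBreakdown,
    CostParameters,
    MaintenanceSchedule,
    MissionProfile,
    SpecialEquipmentProfile,
    average_primary_cost,
    primary_mission_total_cost,
    round_currency,
    step_cost,
    total_cost,
    total_engine_minutes,
    total_starts,
    winch_usages,
)

__all__ = [
    "ScenarioVariation",
    "ScenarioResultRow",
    "CurveResult",
    "builtin_scenarios",
    "get_scenario",
    "load_scenarios",
    "dump_scenarios",
    "cost_table",
    "table_frame",
    "average_cost_curve",
    "perturbed_variation",
    "TABLE_COLUMNS",
]

SCENARIO_IDS = [f"{s}.{v}" for s in (1, 2, 3) for v in ("I", "II", "III", "IV", "V")]

TABLE_COLUMNS = [
    "scenario",
    "x",
    "y",
    "z",
    "w",
    "avg_fixed",
    "avg_personnel",
    "avg_maintenance",
    "avg_variable",
    "avg_total",
    "primary_total",
    "total",
]

# long config aliases accepted next to the single-letter symbols
_PARAM_ALIASES = {
    "fixed_costs_eur": "a",
    "personnel_costs_eur": "p",
    "daytime_personnel_share": "q",
    "material_primary_eur": "i",
    "material_secondary_eur": "j",
    "fuel_eur_per_minute": "l",
    "starts_per_mission": "t",
    "primary_area_km2": "beta",
    "secondary_area_km2": "gamma",
    "tariff_eur_per_minute": "price_per_minute",
}
_SPECIAL_ALIASES = {
    "special_share": "alpha",
    "start_correction": "m",
    "duration_correction": "n",
    "training_starts": "r",
    "training_minutes": "s",
    "special_personnel_eur": "o",
    "special_fixed_eur": "v",
}


def _parse_ratio(value: Union[int, float, str]) -> float:
    """Accept 1, 0.5714... or a fraction string like "4/7"."""
    if isinstance(value, str):
        return float(Fraction(value.replace(" ", "")))
    return float(value)


def _apply_aliases(mapping: Mapping[str, object], aliases: Mapping[str, str]) -> dict:
    out = {}
    for key, value in mapping.items():
        out[aliases.get(key, key)] = value
    return out


@dataclass(frozen=True)
class ScenarioVariation:
    """One scenario-variation: parameters plus the fixed mission background.

    ``base_profile`` carries the night-primary and secondary mission counts
    (y, z, w) and the billable durations; the daytime primary count x is free
    and supplied per evaluation through :meth:`profile`.
    """

    id: str
    params: CostParameters
    base_profile: MissionProfile
    description: str = ""

    def profile(self, x: int) -> MissionProfile:
        return self.base_profile.with_x(x)


@dataclass(frozen=True)
class ScenarioResultRow:
    """One row of a cost-overview table (unrounded euro values)."""

    id: str
    x: int
    y: int
    z: int
    w: int
    averages: AverageCostBreakdown
    primary_total: float
    total: float


@dataclass(frozen=True)
class CurveResult:
    """Average-cost curve over integer mission counts.

    ``points`` is the per-x sequence ``(x, avg_total)``; ``jumps`` lists the x
    at which total maintenance cost rises, i.e. where a maintenance interval
    threshold is crossed and the otherwise falling curve jumps upward.
    """

    scenario: str
    points: tuple[tuple[int, float], ...]
    jumps: tuple[int, ...]


# ---------------------------------------------------------------------------
# fixture loading / serialization
# ---------------------------------------------------------------------------


def _variation_from_config(
    vid: str, spec: Mapping[str, object], shared: Mapping[str, object]
) -> ScenarioVariation:
    merged: dict = dict(_apply_aliases(shared, _PARAM_ALIASES))
    merged.update(_apply_aliases(spec, _PARAM_ALIASES))
    description = str(merged.pop("description", ""))
    profile_spec = dict(merged.pop("profile", {}))
    schedule = MaintenanceSchedule(
        start_intervals=tuple((t, c) for t, c in merged.pop("start_intervals", ())),
        flighttime_intervals=tuple((t, c) for t, c in merged.pop("flighttime_intervals", ())),
        winch_intervals=tuple((t, c) for t, c in merged.pop("winch_intervals", ())),
    )
    special_spec = _apply_aliases(dict(merged.pop("special", {})), _SPECIAL_ALIASES)
    special = SpecialEquipmentProfile(**{k: v for k, v in special_spec.items()})
    params = CostParameters(
        a=float(merged["a"]),
        p=float(merged["p"]),
        q=_parse_ratio(merged.get("q", 1)),
        i=float(merged.get("i", 120.0)),
        j=float(merged.get("j", 170.0)),
        l=float(merged.get("l", 5.83)),
        t=int(merged.get("t", 2)),
        beta=float(merged.get("beta", 11550.0)),
        gamma=float(merged.get("gamma", 23000.0)),
        schedule=schedule,
        special=special,
        price_per_minute=float(merged.get("price_per_minute", 70.0)),
    )
    base_profile = MissionProfile(
        x=0,
        y=int(profile_spec.get("y", 0)),
        z=int(profile_spec.get("z", 0)),
        w=int(profile_spec.get("w", 0)),
        b_x=float(merged.get("b_x", 20.0)),
        b_y=float(merged.get("b_y", 20.0)),
        b_z=float(merged.get("b_z", 45.0)),
        b_w=float(merged.get("b_w", 45.0)),
    )
    return ScenarioVariation(id=vid, params=params, base_profile=base_profile, description=description)


def load_scenarios(source: Union[str, TextIO, Mapping]) -> list[ScenarioVariation]:
    """Load scenario variations from a YAML document, path or parsed mapping."""
    if isinstance(source, Mapping):
        doc = dict(source)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as handle:
            doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping) or "scenarios" not in doc:
        raise ValueError("scenario file must contain a top-level 'scenarios' mapping")
    shared = dict(doc.get("shared", {}))
    variations = [
        _variation_from_config(vid, spec, shared) for vid, spec in dict(doc["scenarios"]).items()
    ]
    seen = set()
    for var in variations:
        if var.id in seen:
            raise ValueError(f"duplicate scenario id {var.id!r}")
        seen.add(var.id)
    return variations


def dump_scenarios(variations: Iterable[ScenarioVariation]) -> str:
    """Serialize variations to the YAML config dialect (lossless round trip)."""
    doc: dict = {"scenarios": {}}
    for var in variations:
        p = var.params
        entry: dict = {
            "description": var.description,
            "a": p.a,
            "p": p.p,
            "q": p.q,
            "i": p.i,
            "j": p.j,
            "l": p.l,
            "t": p.t,
            "beta": p.beta,
            "gamma": p.gamma,
            "price_per_minute": p.price_per_minute,
            "b_x": var.base_profile.b_x,
            "b_y": var.base_profile.b_y,
            "b_z": var.base_profile.b_z,
            "b_w": var.base_profile.b_w,
            "profile": {
                "y": var.base_profile.y,
                "z": var.base_profile.z,
                "w": var.base_profile.w,
            },
            "start_intervals": [list(iv) for iv in p.schedule.start_intervals],
            "flighttime_intervals": [list(iv) for iv in p.schedule.flighttime_intervals],
            "winch_intervals": [list(iv) for iv in p.schedule.winch_intervals],
        }
        sp = p.special
        if sp.active:
            entry["special"] = {
                "alpha": sp.alpha,
                "m": sp.m,
                "n": sp.n,
                "r": sp.r,
                "s": sp.s,
                "o": sp.o,
                "v": sp.v,
            }
        doc["scenarios"][var.id] = entry
    return yaml.safe_dump(doc, sort_keys=False)


_BUILTIN_CACHE: Optional[list[ScenarioVariation]] = None


def builtin_scenarios() -> list[ScenarioVariation]:
    """The 15 built-in scenario variations (fresh copies of cached parse)."""
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        text = resources.files("hemscost").joinpath("data/scenarios.yaml").read_text("utf-8")
        variations = load_scenarios(yaml.safe_load(text))
        order = {vid: pos for pos, vid in enumerate(SCENARIO_IDS)}
        variations.sort(key=lambda v: order.get(v.id, len(order)))
        _BUILTIN_CACHE = variations
    return list(_BUILTIN_CACHE)


def get_scenario(scenario_id: str) -> ScenarioVariation:
    for var in builtin_scenarios():
        if var.id == scenario_id:
            return var
    raise KeyError(f"unknown scenario id {scenario_id!r}; known: {', '.join(SCENARIO_IDS)}")


# ---------------------------------------------------------------------------
# tables and curves
# ---------------------------------------------------------------------------


def cost_table(
    variations: Union[ScenarioVariation, Sequence[ScenarioVariation]],
    x_values: Sequence[int],
    *,
    secondary_material_mode: str = "formula",
    fixed_denominator: str = "primary_minutes",
    daytime_personnel_cost: Optional[float] = None,
) -> list[ScenarioResultRow]:
    """Evaluate the cost-overview table: one row per (variation, x)."""
    if isinstance(variations, ScenarioVariation):
        variations = [variations]
    if not x_values:
        raise ValueError("x_values must be nonempty")
    if any(x < 1 for x in x_values):
        raise ValueError("every x must be >= 1")
    rows = []
    for var in variations:
        for x in x_values:
            profile = var.profile(x)
            avg = average_primary_cost(
                var.params,
                profile,
                fixed_denominator=fixed_denominator,
                daytime_personnel_cost=daytime_personnel_cost,
            )
            rows.append(
                ScenarioResultRow(
                    id=var.id,
                    x=x,
                    y=profile.y,
                    z=profile.z,
                    w=profile.w,
                    averages=avg,
                    primary_total=primary_mission_total_cost(
                        var.params,
                        profile,
                        fixed_denominator=fixed_denominator,
                        daytime_personnel_cost=daytime_personnel_cost,
                    ),
                    total=total_cost(
                        var.params, profile, secondary_material_mode=secondary_material_mode
                    ).total,
                )
            )
    return rows


def table_frame(rows: Sequence[ScenarioResultRow]) -> pd.DataFrame:
    """Rows as a DataFrame with 2-decimal currency, column order as published."""
    records = []
    for row in rows:
        avg = row.averages
        records.append(
            {
                "scenario": row.id,
                "x": row.x,
                "y": row.y,
                "z": row.z,
                "w": row.w,
                "avg_fixed": round_currency(avg.avg_fixed),
                "avg_personnel": round_currency(avg.avg_personnel),
                "avg_maintenance": round_currency(avg.avg_maintenance),
                "avg_variable": round_currency(avg.avg_variable),
                "avg_total": round_currency(avg.avg_total),
                "primary_total": round_currency(row.primary_total),
                "total": round_currency(row.total),
            }
        )
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def _maintenance_level(var: ScenarioVariation, x: int) -> float:
    """Raw annual maintenance euro at mission count x (all three families)."""
    profile = var.profile(x)
    schedule = var.params.schedule
    return (
        step_cost(total_starts(var.params, profile), schedule.start_intervals)
        + step_cost(total_engine_minutes(var.params, profile).total, schedule.flighttime_intervals)
        + step_cost(winch_usages(var.params, profile), schedule.winch_intervals)
    )


def average_cost_curve(
    variation: ScenarioVariation,
    x_min: int,
    x_max: int,
    *,
    fixed_denominator: str = "primary_minutes",
    daytime_personnel_cost: Optional[float] = None,
) -> CurveResult:
    """Average cost per primary mission for every integer x in [x_min, x_max].

    Missions are indivisible, so the curve is evaluated per integer x only.
    An x is flagged as a jump when the raw maintenance cost exceeds the level
    at x-1 (a maintenance interval multiple was crossed); between flagged
    points the curve falls strictly (fixed-cost digression).
    """
    if not 1 <= x_min <= x_max:
        raise ValueError("need 1 <= x_min <= x_max")
    points = []
    jumps = []
    previous_level = _maintenance_level(variation, x_min - 1) if x_min > 1 else None
    for x in range(x_min, x_max + 1):
        avg = average_primary_cost(
            variation.params,
            variation.profile(x),
            fixed_denominator=fixed_denominator,
            daytime_personnel_cost=daytime_personnel_cost,
        )
        points.append((x, avg.avg_total))
        level = _maintenance_level(variation, x)
        if previous_level is not None and level > previous_level:
            jumps.append(x)
        previous_level = level
    return CurveResult(scenario=variation.id, points=tuple(points), jumps=tuple(jumps))


# ---------------------------------------------------------------------------
# perturbed fixtures for property tests
# ---------------------------------------------------------------------------


def perturbed_variation(
    base: ScenarioVariation,
    rng: random.Random,
    *,
    relative_spread: float = 0.3,
) -> ScenarioVariation:
    """A randomly perturbed but valid variation derived from ``base``.

    Cost levels and thresholds are jittered multiplicatively within
    ``1 +/- relative_spread`` while preserving every type invariant
    (ordered thresholds, nonnegative costs, valid shares); used to exercise
    model properties away from the published parameter sets.
    """

    def jitter(value: float, low: float = 0.0) -> float:
        return max(low, value * rng.uniform(1.0 - relative_spread, 1.0 + relative_spread))

    def jitter_intervals(intervals):
        out = []
        last = 0.0
        for threshold, price in intervals:
            threshold = max(last + 1.0, jitter(threshold))
            out.append((threshold, jitter(price)))
            last = threshold
        return tuple(out)

    p = base.params
    schedule = MaintenanceSchedule(
        start_intervals=jitter_intervals(p.schedule.start_intervals),
        flighttime_intervals=jitter_intervals(p.schedule.flighttime_intervals),
        winch_intervals=jitter_intervals(p.schedule.winch_intervals),
    )
    sp = p.special
    special = replace(
        sp,
        o=jitter(sp.o),
        v=jitter(sp.v),
        alpha=min(1.0, jitter(sp.alpha)) if sp.active else 0.0,
    )
    params = replace(
        p,
        a=jitter(p.a),
        p=jitter(p.p),
        i=jitter(p.i),
        j=jitter(p.j),
        l=jitter(p.l),
        schedule=schedule,
        special=special,
    )
    profile = replace(
        base.base_profile,
        z=rng.randint(0, 500),
        w=base.base_profile.w and rng.randint(0, 300),
    )
    return ScenarioVariation(
        id=f"{base.id}*", params=params, base_profile=profile, description="perturbed"
    )
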