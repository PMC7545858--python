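"""Revenue model and break-even analysis.

Revenue is a flat tariff ``P`` per billable flight minute; training flights
are not billable.  Profit at a given number ``x`` of daytime primary missions
(secondary and night missions held constant by the scenario) is revenue minus
total annual cost.  Because maintenance cost is jump-fixed, profit is affine
in x between interval crossings and drops by the triggered interval price at
each crossing — a mission count can be transiently profitable and fall back
into loss at the next maintenance jump.  The sustainable break-even point is
therefore the smallest x whose profit stays nonnegative for every larger x in
the scanned range; earlier sign changes are reported as transient crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cost_model import CostParameters, MissionProfile, total_cost
from .scenario_engine import ScenarioVariation

__all__ = ["BreakEvenResult", "revenue", "break_even"]


@dataclass(frozen=True)
class ProfitPoint:
    x: int
    revenue: float
    total_cost: float

    @property
    def profit(self) -> float:
        return self.revenue - self.total_cost


@dataclass(frozen=True)
class BreakEvenResult:
    """Outcome of a profit scan over a range of primary-mission counts.

    ``x_star`` is the sustainable break-even (smallest x with profit >= 0
    that never falls below 0 again within the scanned range), or ``None``
    when no such x exists in range.  ``transient_crossings`` lists the x at
    which profit first turns nonnegative but is later pushed negative again
    by a maintenance jump.
    """

    scenario: str
    price_per_minute: float
    x_star: Optional[int]
    transient_crossings: tuple[int, ...]
    profit_curve: tuple[ProfitPoint, ...]

    @property
    def attained(self) -> bool:
        return self.x_star is not None


def revenue(params: CostParameters, profile: MissionProfile, *, price: Optional[float] = None) -> float:
    """Annual revenue ``P * billable minutes``.

    Billable minutes are the mission minutes
    ``(1-alpha)*x*b_x + alpha*b_x*x*n + y*b_y + z*b_z + w*b_w``; training
    minutes ``r*s`` earn nothing.
    """
    tariff = params.price_per_minute if price is None else float(price)
    if tariff < 0:
        raise ValueError("tariff must be >= 0")
    sp = params.special
    if sp.active:
        primary_minutes = (1.0 - sp.alpha) * profile.x * profile.b_x + sp.alpha * profile.b_x * profile.x * sp.n
    else:
        primary_minutes = profile.x * profile.b_x
    other = profile.y * profile.b_y + profile.z * profile.b_z + profile.w * profile.b_w
    return tariff * (primary_minutes + other)


def break_even(
    variation: ScenarioVariation,
    price: Optional[float] = None,
    x_range: Sequence[int] = range(1, 2001),
    *,
    secondary_material_mode: str = "formula",
) -> BreakEvenResult:
    """Scan profit over ``x_range`` and locate the sustainable break-even.

    ``x_range`` must be a nonempty ascending sequence of integers >= 0.
    Equality counts as break-even (profit >= 0).  Deterministic: the result
    is a pure function of the variation, tariff and range.
    """
    xs = list(x_range)
    if not xs:
        raise ValueError("x_range must be nonempty")
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError("x_range must be strictly ascending")
    if xs[0] < 0:
        raise ValueError("x_range values must be >= 0")

    tariff = variation.params.price_per_minute if price is None else float(price)
    curve = []
    for x in xs:
        profile = variation.profile(x)
        curve.append(
            ProfitPoint(
                x=x,
                revenue=revenue(variation.params, profile, price=tariff),
                total_cost=total_cost(
                    variation.params, profile, secondary_material_mode=secondary_material_mode
                ).total,
            )
        )

    # suffix scan: nonneg_from[i] <=> profit >= 0 at every scanned x >= xs[i]
    nonneg_from = [False] * len(curve)
    ok = True
    for idx in range(len(curve) - 1, -1, -1):
        ok = ok and curve[idx].profit >= 0
        nonneg_from[idx] = ok

    x_star = next((pt.x for pt, good in zip(curve, nonneg_from) if good), None)
    transients = tuple(
        pt.x
        for idx, pt in enumerate(curve)
        if pt.profit >= 0
        and (idx == 0 or curve[idx - 1].profit < 0)
        and not nonneg_from[idx]
    )
    return BreakEvenResult(
        scenario=variation.id,
        price_per_minute=tariff,
        x_star=x_star,
        transient_crossings=transients,
        profit_curve=tuple(curve),
    )
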