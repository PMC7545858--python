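"""Unit tests of the annual and per-mission cost functions."""

import random
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemscost import (
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
)

STANDARD_STARTS = ((200, 4200.0), (400, 8000.0), (1200, 50000.0), (2400, 100000.0))


# ---------------------------------------------------------------------------
# step_cost
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "amount, expected",
    [
        (2584, 298_400.0),  # 12*4200 + 6*8000 + 2*50000 + 1*100000
        (199, 0.0),
        (200, 4_200.0),
        (0, 0.0),
    ],
)
def test_step_cost_start_ladder(amount, expected):
    assert step_cost(amount, STANDARD_STARTS) == expected


def test_step_cost_rejects_bad_input():
    with pytest.raises(ValueError):
        step_cost(-1, STANDARD_STARTS)
    with pytest.raises(ValueError):
        step_cost(10, [(100, 5.0), (100, 7.0)])  # duplicate threshold
    with pytest.raises(ValueError):
        step_cost(10, [(0, 5.0)])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    intervals=st.lists(
        st.tuples(st.integers(min_value=1, max_value=60), st.floats(0, 1000)),
        min_size=1,
        max_size=4,
        unique_by=lambda pair: pair[0],
    ),
    amount=st.integers(min_value=0, max_value=10_000),
)
def test_step_cost_matches_unit_accumulation_oracle(intervals, amount):
    from conftest import step_cost_unit_oracle

    assert step_cost(amount, intervals) == pytest.approx(
        step_cost_unit_oracle(amount, intervals)
    )


def test_step_cost_is_monotone_and_jumps_at_multiples():
    ladder = ((5, 10.0), (12, 100.0))
    values = [step_cost(a, ladder) for a in range(0, 121)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    jump_points = [a for a in range(1, 121) if values[a] > values[a - 1]]
    assert jump_points == sorted({m for m in range(1, 121) if m % 5 == 0 or m % 12 == 0})


# ---------------------------------------------------------------------------
# activity counters
# ---------------------------------------------------------------------------


def test_total_starts_standard_profile(scenarios):
    var = scenarios["1.I"]
    assert total_starts(var.params, var.profile(1200)) == 2584  # 2*(1200+92)


def test_total_starts_empty_year(scenarios):
    var = scenarios["1.I"]
    profile = MissionProfile(x=0, y=0, z=0, w=0)
    assert total_starts(var.params, profile) == 0


def test_total_starts_special_equipment_correction(scenarios):
    # winch missions take m=0.5 starts corrections plus r training starts
    var = scenarios["1.V"]
    profile = MissionProfile(x=1200)  # primaries only
    assert total_starts(var.params, profile) == pytest.approx(100 + 2160 + 120)


def test_engine_minutes_standard_profile(scenarios):
    var = scenarios["1.I"]
    minutes = total_engine_minutes(var.params, var.profile(1200))
    assert minutes.primary == 24_000
    assert minutes.other == 4_140
    assert minutes.training == 0
    assert minutes.total == 28_140


def test_engine_minutes_special_equipment(scenarios):
    var = scenarios["1.V"]
    minutes = total_engine_minutes(var.params, var.profile(1200))
    assert minutes.training == pytest.approx(6_000)
    assert minutes.primary == pytest.approx(26_400)  # 0.9*24000 + 0.1*48000
    assert minutes.other == pytest.approx(4_140)
    assert minutes.total == pytest.approx(36_540)


def test_engine_minutes_empty_year(scenarios):
    var = scenarios["1.I"]
    assert total_engine_minutes(var.params, MissionProfile(x=0)).total == 0


# ---------------------------------------------------------------------------
# total annual cost
# ---------------------------------------------------------------------------


def test_total_cost_components_initial_scenario(scenarios):
    var = scenarios["1.I"]
    breakdown = total_cost(var.params, var.profile(1200))
    assert breakdown.fixed == 316_450
    assert breakdown.personnel == 724_000
    assert breakdown.maintenance_starts == 298_400
    assert breakdown.maintenance_flighttime == 35_000
    assert breakdown.maintenance_winch == 0
    assert breakdown.material == pytest.approx(120 * 1200 + 170 * 92)
    assert breakdown.fuel == pytest.approx(5.83 * 28_140)
    assert round_currency(breakdown.total) == 1_697_546.20


def test_total_cost_secondary_material_modes(scenarios):
    var = scenarios["1.I"]
    formula = total_cost(var.params, var.profile(900)).total
    table = total_cost(var.params, var.profile(900), secondary_material_mode="table").total
    assert round_currency(formula) == 1_442_966.20
    assert round_currency(table) == 1_438_366.20
    assert formula - table == pytest.approx((170 - 120) * 92)
    with pytest.raises(ValueError):
        total_cost(var.params, var.profile(900), secondary_material_mode="nope")


def test_total_cost_empty_year_keeps_output_independent_terms(scenarios):
    # with no missions only a, p, o, v remain (training gated on alpha > 0)
    params = scenarios["1.IV"].params
    params = replace(params, special=replace(params.special, r=0))
    breakdown = total_cost(params, MissionProfile(x=0))
    sp = params.special
    assert breakdown.total == pytest.approx(params.a + params.p + sp.o + sp.v)


def test_breakdown_total_is_component_sum(scenarios):
    for var in scenarios.values():
        breakdown = total_cost(var.params, var.profile(1200))
        explicit = (
            breakdown.fixed
            + breakdown.personnel
            + breakdown.special_personnel
            + breakdown.special_fixed
            + breakdown.maintenance
            + breakdown.material
            + breakdown.fuel
        )
        assert breakdown.total == pytest.approx(explicit, abs=0.01)
        assert min(
            breakdown.fixed, breakdown.personnel, breakdown.material, breakdown.fuel
        ) >= 0


def test_total_cost_invariant_under_interval_permutation(scenarios):
    var = scenarios["1.II"]
    rng = random.Random(7)
    shuffled_starts = list(var.params.schedule.start_intervals)
    shuffled_flight = list(var.params.schedule.flighttime_intervals)
    rng.shuffle(shuffled_starts)
    rng.shuffle(shuffled_flight)
    permuted = replace(
        var.params,
        schedule=MaintenanceSchedule(
            start_intervals=tuple(shuffled_starts),
            flighttime_intervals=tuple(shuffled_flight),
        ),
    )
    assert total_cost(permuted, var.profile(1200)).total == total_cost(
        var.params, var.profile(1200)
    ).total


def test_inert_special_profile_matches_standard_operations(scenarios):
    # alpha = 0 must silence every special term, r/s/o/v included
    base = scenarios["1.I"]
    quiet_special = SpecialEquipmentProfile(alpha=0.0, m=1.5, n=2.0, r=300, s=20.0, o=10_000, v=39_980)
    params = replace(base.params, special=quiet_special)
    profile = base.profile(1200)
    assert total_cost(params, profile) == total_cost(base.params, profile)
    assert average_primary_cost(params, profile) == average_primary_cost(base.params, profile)


# ---------------------------------------------------------------------------
# average cost per primary mission
# ---------------------------------------------------------------------------


def test_average_cost_initial_scenario_components(scenarios):
    avg = average_primary_cost(scenarios["1.I"].params, scenarios["1.I"].profile(1200))
    assert round_currency(avg.avg_fixed) == 88.16
    assert round_currency(avg.avg_personnel) == 201.69
    assert round_currency(avg.avg_maintenance) == 236.96
    assert round_currency(avg.avg_variable) == 236.60
    assert round_currency(avg.avg_total) == 763.41


@pytest.mark.parametrize("x, expected", [(900, 758.39), (1200, 763.41), (1500, 678.79)])
def test_average_cost_sweep_initial_scenario(scenarios, x, expected):
    avg = average_primary_cost(scenarios["1.I"].params, scenarios["1.I"].profile(x))
    assert round_currency(avg.avg_total) == expected


def test_average_cost_special_equipment_cells(scenarios):
    # winch: (o+v) spread over CEIL(alpha*x) equipped missions, weight alpha
    avg_v = average_primary_cost(scenarios["1.V"].params, scenarios["1.V"].profile(1200))
    assert round_currency(avg_v.avg_fixed) == 204.81
    assert round_currency(avg_v.avg_variable) == 248.26
    avg_iv = average_primary_cost(scenarios["1.IV"].params, scenarios["1.IV"].profile(1200))
    assert round_currency(avg_iv.avg_fixed) == 129.81
    assert round_currency(avg_iv.avg_variable) == 242.43


def test_average_cost_alternate_readings(scenarios):
    # dual-use fixed cost over daytime minutes; 24-h personnel override
    avg = average_primary_cost(
        scenarios["3.III"].params,
        scenarios["3.III"].profile(1200),
        fixed_denominator="daytime_minutes",
    )
    assert round_currency(avg.avg_fixed) == 53.88
    avg = average_primary_cost(
        scenarios["3.I"].params,
        scenarios["3.I"].profile(1200),
        daytime_personnel_cost=724_000,
    )
    assert round_currency(avg.avg_personnel) == 201.69


def test_average_cost_rejects_empty_year(scenarios):
    with pytest.raises(ValueError):
        average_primary_cost(scenarios["1.I"].params, scenarios["1.I"].profile(0))


# ---------------------------------------------------------------------------
# primary-remit allocated total
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("x, expected", [(900, 682_549.10), (1200, 916_090.16)])
def test_primary_mission_total_cost_cells(scenarios, x, expected):
    value = primary_mission_total_cost(scenarios["1.I"].params, scenarios["1.I"].profile(x))
    assert round_currency(value) == expected


def test_primary_total_single_mission_identity(scenarios):
    var = scenarios["1.I"]
    avg = average_primary_cost(var.params, var.profile(1))
    assert primary_mission_total_cost(var.params, var.profile(1)) == pytest.approx(
        avg.avg_total
    )


def test_allocation_key_conserves_fixed_cost(scenarios):
    for var in scenarios.values():
        p = var.params
        assert p.primary_share + p.secondary_share == pytest.approx(1.0, abs=1e-12)
        assert p.a * p.primary_share + p.a * p.secondary_share == pytest.approx(
            p.a, abs=1e-6
        )


# ---------------------------------------------------------------------------
# type invariants
# ---------------------------------------------------------------------------


def test_domain_type_validation():
    with pytest.raises(ValueError):
        MissionProfile(x=-1)
    with pytest.raises(TypeError):
        MissionProfile(x=1.5)
    with pytest.raises(ValueError):
        MissionProfile(x=1, b_x=0)
    with pytest.raises(ValueError):
        SpecialEquipmentProfile(alpha=1.5)
    with pytest.raises(ValueError):
        SpecialEquipmentProfile(alpha=0.1, m=0)
    with pytest.raises(ValueError):
        CostParameters(a=-1, p=0)
    with pytest.raises(ValueError):
        CostParameters(a=0, p=0, q=0)
    with pytest.raises(ValueError):
        MaintenanceSchedule(start_intervals=((200, 1.0),) * 5)


def test_round_currency_half_up():
    assert round_currency(1.005) == 1.01
    assert round_currency(2.675) == 2.68
    assert round_currency(-1.005) == -1.01
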