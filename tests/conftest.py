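import pytest

from hemscost import builtin_scenarios


@pytest.fixture(scope="session")
def scenarios():
    """Built-in scenario variations keyed by id."""
    return {var.id: var for var in builtin_scenarios()}


def step_cost_unit_oracle(amount, intervals):
    """Brute-force jump-fixed cost: accumulate the activity one unit at a
    time and charge each interval price whenever its counter reaches the
    threshold.  Integer thresholds and amounts only."""
    total = 0.0
    counters = {threshold: 0 for threshold, _ in intervals}
    for _ in range(int(amount)):
        for threshold, price in intervals:
            counters[threshold] += 1
            if counters[threshold] == threshold:
                total += price
                counters[threshold] = 0
    return total


@pytest.fixture(scope="session")
def step_oracle():
    return step_cost_unit_oracle
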