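import pytest

import htnscreen as hs


@pytest.fixture(scope="session")
def base_params():
    """Full 70-cycle base case with synthetic schedules (seed 1)."""
    return hs.base_case(schedule_seed=1)


@pytest.fixture()
def reduced_params(base_params):
    """10-cycle truncation of the base case, for Monte-Carlo comparisons."""
    return base_params.with_value("config.n_cycles", 10)


@pytest.fixture(scope="session")
def roster():
    return hs.strategy_roster()


@pytest.fixture(scope="session")
def base_results(base_params, roster):
    """Lifetime discounted (cost, QALY) per strategy on the base case."""
    return [hs.evaluate_strategy(s, base_params) for s in roster]
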