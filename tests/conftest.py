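import pytest

from shrimpn import datasets, dynamics
from shrimpn.budget import build_budget_table


@pytest.fixture(scope="session")
def scenarios():
    return datasets.gomishan_scenarios()


@pytest.fixture(scope="session")
def budget_tables(scenarios):
    return {key: build_budget_table(s, convention="table1") for key, s in scenarios.items()}


@pytest.fixture(scope="session")
def trajectory_2018():
    return dynamics.simulate(dynamics.StellaParams())


@pytest.fixture(scope="session")
def trajectory_2021():
    return dynamics.simulate(dynamics.StellaParams(pond_number=1251, init_number=100000))


@pytest.fixture(scope="session")
def foodweb():
    return datasets.foodweb_samples()


def printed_decimals(printed: str) -> int:
    """Number of decimal places in a printed numeric string."""
    return len(printed.split(".")[1]) if "." in printed else 0
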