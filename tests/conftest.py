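import pytest
from hypothesis import settings

import registrygap as rg

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic registry shared by read-only tests."""
    return rg.generate_scenario(rg.ScenarioConfig(seed=1))


@pytest.fixture
def path_graph():
    """A -- B -- C path adjacency."""
    return rg.AdjacencyList.from_dict({"A": {"B"}, "B": {"A", "C"}, "C": {"B"}})


def make_rates(mapping, stratum="female"):
    """Shorthand: {county: rate} -> list of IncidenceRate."""
    return [
        rg.IncidenceRate(county_id=cid, stratum=stratum, rate=float(r))
        for cid, r in mapping.items()
    ]
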