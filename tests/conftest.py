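import json

import pytest
from hypothesis import settings

from woundcea import builtin_paper_scenario, load_scenario, write_scenario

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_scenario():
    """Built-in two-strategy scenario with the moment-matched tariff gamma."""
    return builtin_paper_scenario()


@pytest.fixture(scope="session")
def paper_scenario_as_printed():
    return builtin_paper_scenario(tariff_gamma="as_printed")


def all_fixed(scenario):
    """Point-mass copy of a scenario: every PSA distribution pinned at baseline."""
    doc = json.loads(write_scenario(scenario))
    for strat in doc["strategies"]:
        for key in ("unit_price", "units_per_week", "healing_rate"):
            strat[key]["dist"] = {"family": "fixed", "params": [strat[key]["baseline"]]}
    doc["change_tariff"]["dist"] = {"family": "fixed", "params": [doc["change_tariff"]["baseline"]]}
    return load_scenario(json.dumps(doc))


@pytest.fixture(scope="session")
def paper_scenario_fixed(paper_scenario):
    return all_fixed(paper_scenario)
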