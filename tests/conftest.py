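import pytest

from beefcorridor.scenarios import run_all_scenarios
from beefcorridor.synth import SynthSpec, generate_sam


@pytest.fixture(scope="session")
def synth_sam():
    """One deterministic synthetic SAM shared across tests."""
    return generate_sam(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def scenario_results():
    """All preset corridor scenarios at the default 120-month horizon."""
    return run_all_scenarios()


@pytest.fixture(scope="session")
def baseline(scenario_results):
    return scenario_results["baseline"]
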