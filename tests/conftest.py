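import numpy as np
import pytest

from cismr.simulate import (
    OutcomeModel,
    PanelConfig,
    ScenarioConfig,
    generate_scenario,
    simulate_reference_panel,
)


@pytest.fixture(scope="session")
def panel():
    """Reference panel shared by all tests (the LD reference is fixed in a real study)."""
    return simulate_reference_panel(PanelConfig(seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """Fast low-dimensional panel for unit tests."""
    return simulate_reference_panel(
        PanelConfig(n_individuals=800, n_variants=60, block_size=10, seed=11)
    )


@pytest.fixture(scope="session")
def scenario(panel):
    """One default two-gene scenario with a quantitative outcome, alpha = 0.3."""
    return generate_scenario(
        ScenarioConfig(seed=1, outcomes=[OutcomeModel(alpha=0.3, name="trait_q")]), panel=panel
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
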