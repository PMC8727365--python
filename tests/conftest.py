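import pytest

from dumparts.pipeline import simulate_and_run
from dumparts.simulate import SimConfig, synthetic_germlines


@pytest.fixture(scope="session")
def germlines():
    return synthetic_germlines()


@pytest.fixture(scope="session")
def default_conditions():
    """Study conditions for the end-to-end runs shared across tests.

    Depth / molecule counts give a mean RPUP of 30 for genuine molecules
    (depth per genuine UMI pair), comfortably in the >= 20 regime the RPUP
    filter is designed for.
    """
    return SimConfig(
        seed=11,
        n_samples=4,
        templates_per_sample=30,
        molecules_per_sample=150,
        depth=18000,
        pool_capacity=60000,
    )


@pytest.fixture(scope="session")
def default_run(default_conditions, germlines):
    """One full truth-aware simulate + pipeline run, shared by many tests."""
    result, truth, sim_stats = simulate_and_run(default_conditions, germlines)
    return result, truth, sim_stats
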