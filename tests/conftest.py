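import numpy as np
import pytest

from duomod.simulate import SimulationScenario, generate_scenario


@pytest.fixture(scope="session")
def small_truth():
    """A small but fully featured scenario shared by read-only tests."""
    scenario = SimulationScenario(seed=11, genome_length=120_000, n_genes=24,
                                  n_hyper_m=3, n_hypo_h=3)
    return generate_scenario(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
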