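import numpy as np
import pytest

from ganbalance.simulate import (ExperimentDesign, SimulationConfig,
                                 simulate_two_cluster_dataset, split_experiment)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_two_cluster_dataset(sim_config)


@pytest.fixture(scope="session")
def design9():
    return ExperimentDesign(9, 120, 0.6)


@pytest.fixture(scope="session")
def splits(dataset, sim_config, design9):
    """(real, external, validation) for the largest experiment design."""
    return split_experiment(dataset, design9, sim_config, seed=42)
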