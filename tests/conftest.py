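import logging

import pytest

from tracerflux import TracerBudgetModel
from tracerflux.simulate import NoiseConfig, SimulationConfig, simulate_experiment

# the unclipped-negative-excess warning is expected under noisy nulls and
# would otherwise flood the log
logging.getLogger("tracerflux.isotopes").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Small noiseless experiment: 3 taxa x 2 substrates, 2 animals each."""
    from dataclasses import replace

    config = replace(
        SimulationConfig(seed=11),
        n_animals_per_group=2,
        n_controls=1,
        noise=NoiseConfig.zero(),
    )
    return config, simulate_experiment(config)


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_sim):
    _, sim = zero_noise_sim
    return TracerBudgetModel.from_simulation(sim).fit()


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise experiment at the study's replicate numbers."""
    config = SimulationConfig(seed=5)
    return config, simulate_experiment(config)
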