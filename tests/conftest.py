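import numpy as np
import pytest

from leafphys import default_study_config, simulate_experiment


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def noiseless_config(study_config):
    return study_config.without_noise()


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return simulate_experiment(noiseless_config, seed=7)


@pytest.fixture(scope="session")
def default_bundle(study_config):
    return simulate_experiment(study_config, seed=42)


def spawn_seeds(master: int, n: int) -> list[int]:
    """Deterministic stream of sub-2^31 seeds for replicate simulations."""
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(master).spawn(n)]
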