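import numpy as np
import pytest

import priorank as pr


@pytest.fixture(scope="session")
def toy_genome() -> pr.Genome:
    return pr.Genome([f"g{i}" for i in range(1, 21)], species_label="toy")


@pytest.fixture(scope="session")
def default_dataset() -> pr.SimDataset:
    """One moderate-signal synthetic dataset shared across tests."""
    return pr.simulate(pr.SimConfig(seed=7))


@pytest.fixture(scope="session")
def strong_dataset() -> pr.SimDataset:
    return pr.simulate(pr.SimConfig.strong(seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
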