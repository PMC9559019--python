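import numpy as np
import pytest

from hidmed import HiddenMediatorModel, simulate_dataset, study_config


@pytest.fixture(scope="session")
def small_base_dataset():
    """A base-case replicate small enough for fast tests but large enough
    that the noise/effect clusters of a* and c* separate."""
    cfg = study_config("base", b_H=0.25, p=60, n=8000)
    return simulate_dataset(cfg, seed=123)


@pytest.fixture(scope="session")
def small_base_results(small_base_dataset):
    model = HiddenMediatorModel.from_simulation(small_base_dataset)
    return model.fit(chain_length=4000, burn_in=800, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
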