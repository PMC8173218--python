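import numpy as np
import pytest

from netphys.activations import ActivationDataset
from netphys.synthetic import PlantedSelectivitySpec, gen_activation_dataset


@pytest.fixture(scope="session")
def planted_dataset() -> ActivationDataset:
    """Small dataset with two strongly planted selective channels."""
    spec = PlantedSelectivitySpec(channel_ids=(3, 11), target_category=0,
                                  gain=5.0, noise_sd=0.1)
    return gen_activation_dataset(8, 40, 32, (3, 3), spec, seed=42)


@pytest.fixture(scope="session")
def null_dataset() -> ActivationDataset:
    """Same layout with gain 1: nothing planted."""
    spec = PlantedSelectivitySpec(channel_ids=(3,), target_category=0,
                                  gain=1.0, noise_sd=0.3)
    return gen_activation_dataset(8, 40, 32, (3, 3), spec, seed=43)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
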