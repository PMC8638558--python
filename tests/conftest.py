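import numpy as np
import pytest

from ribostruct.folding import EnergyModel
from ribostruct.simulate import SimulationConfig


@pytest.fixture
def model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast study-condition config for unit tests (defaults otherwise)."""
    return SimulationConfig(seed=11, n_pairs=5, mean_len=150)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
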