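import numpy as np
import pytest

from tumoropt import ModelParameters, make_initial_state

#: typical magnitudes of the 11 compartments, used to sample random
#: admissible states in property tests
STATE_SCALES = np.array(
    [1e7, 2.5e8, 5.268e5, 4.725e7, 1e6, 1.0536e6, 1.795e5, 1.5e3, 1.2e3, 20.0, 1.0]
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture()
def y0_1e7() -> np.ndarray:
    return make_initial_state(1e7, suppression=True)


def random_admissible_state(rng: np.random.Generator) -> np.ndarray:
    """Log-uniform sample around the physiological scales."""
    return STATE_SCALES * np.exp(rng.uniform(np.log(0.2), np.log(5.0), STATE_SCALES.size))
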