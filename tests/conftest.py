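import numpy as np
import pytest

from thzem import FrequencyGrid, study_fractions
from thzem.synthetic import reference_scene


@pytest.fixture(scope="session")
def fractions():
    """Fraction trio for the 334 / 50 mg/mL study conditions."""
    return study_fractions()


@pytest.fixture(scope="session")
def noiseless_scene():
    """Standard noiseless scene over 10-70 cm^-1 at the study fractions."""
    return reference_scene(noise_sd=0.0, seed=0)


@pytest.fixture()
def grid():
    return FrequencyGrid(np.arange(10.0, 71.0, 2.0))
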