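import numpy as np
import pytest

from bssfp2pt import AcquisitionParams, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def acq45():
    return AcquisitionParams(tr=3.2, te=1.2, flip_angle=45.0, rf_duration=0.6)


@pytest.fixture(scope="session")
def acq5(acq45):
    return acq45.with_flip_angle(5.0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-geometry phantom without any noise source."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
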