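import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from lipisf import PeakMatrix, bundled_library
from lipisf.synthdata import default_spec, generate


@pytest.fixture(scope="session")
def library():
    return bundled_library()


@pytest.fixture(scope="session")
def synthetic(library):
    """The reference synthetic conditions (seed 0), shared across tests."""
    return generate(default_spec(seed=0), library)


@pytest.fixture()
def toy_pm():
    """5-pixel, 3-peak matrix with hand-set intensity columns."""
    intensity = np.array(
        [
            [1.0, 2.0, 9.0],
            [2.0, 1.0, 7.0],
            [3.0, 4.0, 5.0],
            [4.0, 3.0, 3.0],
            [5.0, 6.0, 1.0],
        ]
    )
    return PeakMatrix(
        pixels=[(x, 0) for x in range(5)],
        mz=[700.0, 800.0, 900.0],
        intensity=intensity,
    )
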