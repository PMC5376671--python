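import numpy as np
import pytest

import hoxmir as hm


@pytest.fixture(scope="session")
def defaults():
    """Calibrated default parameter bundle (packaged YAML)."""
    return hm.load_defaults()


@pytest.fixture(scope="session")
def wt(defaults):
    return defaults.network_wt


@pytest.fixture(scope="session")
def basal(defaults):
    return defaults.network_basal


@pytest.fixture
def two_species():
    """Hand-specified 2-species chain: A activates B."""
    return hm.NetworkSpec(
        species=("a", "b"),
        gamma=np.array([2.0, 1.0]),
        sigma=5.0,
        basal=np.array([-0.5, -1.0]),
        omega=np.array(
            [
                # a   b   RA  FGF
                [0.0, 0.0, 1.0, 0.0],  # -> a
                [2.0, 0.0, 0.0, 0.0],  # -> b
            ]
        ),
    )


@pytest.fixture
def quiet():
    return hm.NoiseParams(amplitude=0.0)
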