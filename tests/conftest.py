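import numpy as np
import pytest

from camphase import BinarySystem, PcSaftParameters, load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def nap_ind(registry):
    return BinarySystem(registry["NAP"], registry["IND"])


@pytest.fixture(scope="session")
def nap_ibu(registry):
    return BinarySystem(registry["NAP"], registry["IBU"])


@pytest.fixture(scope="session")
def hexane():
    """Literature PC-SAFT parameters of n-hexane (non-associating)."""
    return PcSaftParameters(segment_number=3.0576, segment_diameter=3.7983,
                            dispersion_energy=236.77)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
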