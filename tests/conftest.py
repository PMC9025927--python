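import pytest

from iontunnel import (
    EckartBarrier,
    LeakProfile,
    PhysicalConstants,
    calcium,
    potassium,
    sodium,
)


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def na():
    return sodium()


@pytest.fixture(scope="session")
def kion():
    return potassium()


@pytest.fixture(scope="session")
def ca():
    return calcium()


@pytest.fixture(scope="session")
def leak():
    return LeakProfile()


@pytest.fixture
def barrier():
    """A mid-range closed-gate barrier: G = 2e-20 J, L = 1 angstrom, n = 1."""
    return EckartBarrier(height_G=2e-20, gate_length_L=1e-10, gate_location_n=1)
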