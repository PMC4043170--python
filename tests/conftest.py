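import pytest

from clonewave.params import preset


@pytest.fixture(scope="session")
def haem():
    """Haematopoietic parametrization: 31 compartments, eps 0.85, u 1e-6."""
    return preset("haematopoiesis")


@pytest.fixture(scope="session")
def small():
    """Fast five-compartment hierarchy with inflated mutation rate."""
    return preset("test-small")


@pytest.fixture(scope="session")
def small_hot(small):
    """Small hierarchy with strong mutation flux so multi-mutant classes are
    populated well above solver noise (oracle comparisons)."""
    return small.with_(r0=1.0, u=1e-2, epsilon=0.75)
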