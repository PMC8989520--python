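import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from retroterm.simulate import (  # noqa: E402
    DEFAULT_ADAPTER_A,
    DEFAULT_ADAPTER_B,
    probes_for_reference,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def eco1_like_ref():
    """Synthetic retron reference with an 85-nt canonical RT-DNA (Eco1-like)."""
    return synthetic_reference("Eco1syn", 85, seed=7)


@pytest.fixture(scope="session")
def eco1_probes(eco1_like_ref):
    return probes_for_reference(eco1_like_ref)


@pytest.fixture(scope="session")
def adapters():
    return (DEFAULT_ADAPTER_A, DEFAULT_ADAPTER_B)
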