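import numpy as np
import pytest

from flowflash import FlashTraceConfig, PmfState, default_scheme


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def no_pmf():
    return PmfState(0.0, 0.0)


@pytest.fixture
def smp_pmf():
    """Energized sub-mitochondrial-particle condition: 100 mV, 0.4 pH units."""
    return PmfState(100.0, 0.4)


@pytest.fixture
def quiet_config(no_pmf):
    """Noise-free flash config for deterministic checks."""
    return FlashTraceConfig(pmf=no_pmf, noise_sd=0.0)


def random_linear_chain(rng: np.random.Generator):
    """A random irreversible chain with 3-6 states and rates over 1e1-1e6 s⁻¹."""
    from flowflash import ReactionScheme, Transition

    n = int(rng.integers(3, 7))
    states = tuple(f"S{i}" for i in range(n))
    rates = 10.0 ** rng.uniform(1, 6, n - 1)
    transitions = tuple(Transition(states[i], states[i + 1], float(rates[i]))
                        for i in range(n - 1))
    return ReactionScheme(states=states, transitions=transitions)
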