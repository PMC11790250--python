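import numpy as np
import pytest

from mint import DecoderConfig, Decoder, assemble_library, build_lookup_table, discretize_library_rates
from mint.synthetic import make_world


@pytest.fixture(scope="session")
def small_world():
    return make_world(n_neurons=15, n_conditions=3, duration_ms=400, mean_rate=25.0, seed=42)


@pytest.fixture(scope="session")
def small_library(small_world):
    # window 100 ms at delta=20 -> tau = 99
    return small_world.library(tau=99, delta_ms=20)


@pytest.fixture()
def small_decoder(small_library):
    return Decoder(small_library, DecoderConfig(delta_ms=20, window_ms=100))


def random_library(rng, n_neurons=6, n_conditions=2, length=80, delta=5, tau_prime=3, rate_max=80.0):
    """Random library + matching lookup table / rate index, for oracle tests."""
    rates = {c: rng.uniform(0.0, rate_max, (n_neurons, length)) for c in range(n_conditions)}
    behavior = {c: rng.standard_normal((2, length)) for c in range(n_conditions)}
    lib = assemble_library(rates, behavior, tau=delta * (tau_prime + 1) - 1, delta_ms=delta)
    table = build_lookup_table(0.0, rate_max * 1.5, 0.1, 20, delta)
    return lib, table, discretize_library_rates(lib, table)
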