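import numpy as np
import pytest

from simplirec import (
    ContagionParams,
    GeneratorParams,
    generate_ersc,
    reconstruct,
    simulate_contagion,
)


@pytest.fixture(scope="session")
def medium_instance():
    """A mid-sized random complex, its contagion record, and the full
    two-step reconstruction; shared across tests to amortize the EM cost."""
    truth = generate_ersc(GeneratorParams(n_nodes=50, k1_target=6, k2_target=2, seed=11))
    params = ContagionParams(alpha=0.8, omega=2.4, mu=1.0, rho0=0.2, T=8000, seed=12)
    S = simulate_contagion(truth, params, reseed_on_extinction=True)
    rec = reconstruct(S, seed=13)
    return truth, S, rec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
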