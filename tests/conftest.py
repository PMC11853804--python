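import numpy as np
import pytest

from nested_aif.aif_core import default_mab_model
from nested_aif.fitting import SamplerConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def model():
    """Default three-armed-bandit POMDP at probability matching."""
    return default_mab_model(alpha=1.0)


@pytest.fixture(scope="session")
def short_sampler():
    """Reduced MCMC settings for the test suite (defaults are 4 x 2000)."""
    return SamplerConfig(n_chains=2, n_samples=1500, warmup=600, seed=0)


def random_model(rng, max_states=4, max_obs=3, max_actions=3, max_len=2):
    """A random small valid GenerativeModel (for oracle sweeps)."""
    from nested_aif.aif_core import GenerativeModel

    S = int(rng.integers(2, max_states + 1))
    O = int(rng.integers(2, max_obs + 1))
    U = int(rng.integers(1, max_actions + 1))
    L = int(rng.integers(1, max_len + 1))
    A = rng.dirichlet(np.ones(O), size=S).T
    B = rng.dirichlet(np.ones(S), size=(S, U)).transpose(2, 0, 1)
    C = rng.dirichlet(np.ones(O))
    D = rng.dirichlet(np.ones(S))
    E = rng.dirichlet(np.ones(U**L))
    return GenerativeModel(
        A=A, B=B, C=C, D=D, E=E, policy_len=L,
        gamma=float(rng.uniform(0, 8)), alpha=float(rng.uniform(0, 2)),
    )
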