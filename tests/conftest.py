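import numpy as np
import pytest

from gmftp import (
    FitConfig,
    FunctionalProfile,
    ModelParams,
    PPINetwork,
    fit,
    planted_complex_scenario,
)


@pytest.fixture
def tiny_instance():
    """Smallest nontrivial instance: 2 proteins, 1 complex, 1 term.

    A_12 = 1, F = (1, 0)ᵀ, S = (1, 1), Θ = (1, 1)ᵀ, Ψ = (1), λ = 1.
    Small enough for every quantity to be transcribed by hand.
    """
    net = PPINetwork(protein_ids=["a", "b"], A=np.array([[0, 1], [1, 0]]))
    prof = FunctionalProfile(term_ids=["t"], F=np.array([[1], [0]]),
                             S=np.array([1, 1]))
    params = ModelParams(Theta=np.array([[1.0], [1.0]]), Psi=np.array([[1.0]]),
                         lam=1.0)
    return net, prof, params


@pytest.fixture(scope="session")
def planted_fit():
    """Fitted planted-complex instance shared by pipeline-level tests."""
    net, prof, truth = planted_complex_scenario(seed=0)
    res = fit(net, prof, FitConfig(K=20, lam=4.0, n_restarts=3,
                                   max_iter=200, seed=0))
    return net, prof, truth, res


def random_instance(seed, n=12, k=3, c=5, density=0.3, annotated_fraction=1.0):
    """A small random (network, profile) pair for property tests."""
    rng = np.random.default_rng(seed)
    a = np.triu((rng.random((n, n)) < density).astype(np.int8), k=1)
    a = a | a.T
    s = (rng.random(n) < annotated_fraction).astype(np.int8)
    f = (rng.random((n, c)) < 0.4).astype(np.int8)
    f[s == 0] = 0
    net = PPINetwork(protein_ids=[f"p{i}" for i in range(n)], A=a)
    prof = FunctionalProfile(term_ids=[f"t{j}" for j in range(c)], F=f, S=s)
    params = ModelParams(Theta=rng.uniform(0.05, 1.0, size=(n, k)),
                         Psi=rng.uniform(0.05, 1.0, size=(k, c)), lam=2.0)
    return net, prof, params
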