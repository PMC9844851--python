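import numpy as np
import pytest

import mirtsel as m


@pytest.fixture(scope="session")
def small_instance():
    """A small K=2 dataset with known generating truth."""
    struct = np.array(
        [[1, 0], [0, 1], [1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1], [1, 1], [1, 1]]
    )
    sim = m.SimConfig(N=200, J=10, K=2, seed=21, structure=struct)
    model = m.generate_true_model(sim)
    Y = m.generate_responses(model, 200, seed=22)
    return sim.model_config(), model, Y


@pytest.fixture(scope="session")
def grid11_k2():
    return m.build_grid(11, (-4, 4), 2)


def random_small_problem(rng, N=None, J=None, K=None, per_dim=None):
    """A random tiny instance (params, sigma, Y, grid) for identity checks."""
    N = N or int(rng.integers(5, 51))
    J = J or int(rng.integers(1, 6))
    K = K or int(rng.integers(1, 3))
    per_dim = per_dim or int(rng.integers(2, 6))
    A = rng.normal(0, 1, size=(J, K))
    b = rng.normal(0, 1, size=J)
    rho = rng.uniform(-0.5, 0.5)
    Sigma = np.eye(K) if K == 1 else np.array([[1.0, rho], [rho, 1.0]])
    Y = m.ResponseMatrix((rng.random((N, J)) < 0.5).astype(int))
    grid = m.build_grid(per_dim, (-3, 3), K)
    return m.ItemParams(A, b), m.LatentCov(Sigma), Y, grid
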