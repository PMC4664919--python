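import numpy as np
import pytest

from spikeqp import FeatureBasis, Observation


@pytest.fixture
def gardener():
    """Two-cause worked example: features (1,1) and (1,0)."""
    U = np.array([[1.0, 1.0], [1.0, 0.0]])
    return FeatureBasis(U, norm_flag=False)


@pytest.fixture
def gardener_ambiguous(gardener):
    return gardener, Observation(np.array([2.0, 1.0]))


@pytest.fixture
def gardener_explained(gardener):
    return gardener, Observation(np.array([2.0, 2.0]))


def random_instance(rng, alpha, beta, M=None, N=None):
    """A small random QP instance (unit-norm symmetric-entry basis)."""
    from spikeqp import build_qp, synthesize_observation

    M = int(rng.integers(5, 11)) if M is None else M
    N = int(rng.integers(8, 13)) if N is None else N
    U = rng.uniform(-0.5, 0.5, (M, N))
    U = U / np.linalg.norm(U, axis=0)
    basis = FeatureBasis(U)
    r_true = np.where(rng.random(N) < 0.3, rng.uniform(0, 5, N), 0.0)
    obs = synthesize_observation(basis, r_true, noise_sd=0.1,
                                 seed=int(rng.integers(2**31)))
    return build_qp(basis, obs, alpha, beta)
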