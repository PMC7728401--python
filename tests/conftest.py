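import numpy as np
import pytest

from cilva.core import CilvaModel, FluorescenceMatrix, StimulusDesign, make_kernel
from cilva.simulate import simulate, zebrafish_like


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def kernel():
    return make_kernel(2.0, 5.0, max_len=200)


@pytest.fixture
def small_instance(rng, kernel):
    """A small random model + data pair for oracle checks (not a fit)."""
    N, K, L, T = 4, 3, 2, 80
    S = np.zeros((K, T))
    for j, t in enumerate(range(3, T, 11)):
        S[j % K, t] = 1.0
    design = StimulusDesign(S)
    model = CilvaModel(
        alpha=rng.uniform(0.5, 3.0, N),
        beta=rng.uniform(0.0, 0.5, N),
        W=rng.uniform(0.0, 1.0, (N, K)),
        B=rng.uniform(0.0, 1.0, (N, L)),
        X=rng.uniform(0.0, 1.0, (L, T)),
        sigma2=rng.uniform(0.05, 0.3, N),
        gamma=0.8,
        kernel=kernel,
    )
    F = FluorescenceMatrix(rng.normal(0.0, 1.0, (N, T)) + 0.5, fs=2.0)
    return F, model, design


@pytest.fixture(scope="session")
def tiny_truth():
    """Small simulated population reused by fast integration tests."""
    return simulate(zebrafish_like(N=8, T=400, seed=11))
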