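import numpy as np
import pytest

from metaviz import candidates as cand
from metaviz import core, simulate as sim

# fast, deterministic subset of the registry used where the full 16-candidate
# ensemble would dominate the runtime
FAST_NAMES = ("pca", "mds", "imds", "sammon", "lle", "isomap1", "kpca1", "leim")


def fast_specs(seed: int = 0):
    return [s for s in cand.default_registry(seed=seed) if s.name in FAST_NAMES]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrices():
    """Two 3-sample candidates with hand-computable normalized rows.

    Candidate A: points (0,0), (1,0), (0,2) -> row 0 = (0, 1/sqrt5, 2/sqrt5).
    Candidate B: points (0,0), (1,0), (0,1) -> row 0 = (0, 1/sqrt2, 1/sqrt2).
    """
    A = core.normalize_distances(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]]))
    B = core.normalize_distances(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
    return A, B


@pytest.fixture(scope="session")
def mixture_dataset():
    """Small orthogonal-mixture dataset at comfortable SNR."""
    return sim.gaussian_mixture_signals(n=90, p=60, theta=6.0, seed=7)


@pytest.fixture(scope="session")
def fast_ensemble(mixture_dataset):
    """Fast-registry embeddings of the small mixture dataset."""
    return cand.run_registry(mixture_dataset.observations, fast_specs(seed=7))


@pytest.fixture(scope="session")
def fast_matrices(fast_ensemble):
    d = fast_ensemble.normalized_distances()
    names = list(d)
    return names, [d[k] for k in names]
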