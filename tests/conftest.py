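import numpy as np
import pytest

from msnr import CovariateTable, build_membership
from msnr.core import AdjacencyStack


def random_symmetric_stack(rng, n, p, scale=1.0):
    """Random symmetric zero-diagonal stack."""
    vals = np.zeros((n, p, p))
    iu = np.triu_indices(p, k=1)
    for i in range(n):
        vals[i][iu] = rng.normal(0.0, scale, size=iu[0].size)
        vals[i] += vals[i].T
    return AdjacencyStack(vals)


def random_instance(seed, n=5, p=6, K=2, q=2, scale=1.0):
    """Small random (A, X, partition) triple for solver tests."""
    rng = np.random.default_rng(seed)
    A = random_symmetric_stack(rng, n, p, scale)
    X = CovariateTable(rng.normal(size=(n, q)))
    labels = [f"c{j % K}" for j in range(p)]
    part = build_membership(
        dict(zip([f"n{j:04d}" for j in range(p)], labels)),
        [f"n{j:04d}" for j in range(p)],
    )
    return A, X, part


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance():
    return random_instance(7)
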