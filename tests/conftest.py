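import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from latentmap import ContingencyTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_table(rng, n, n_pairs=1000, sparsity=0.0):
    """A random contingency table: Dirichlet joint frequencies, optionally
    zeroing a fraction of cells (renormalized)."""
    C = rng.dirichlet(np.ones(n * n)).reshape(n, n)
    if sparsity > 0:
        drop = rng.random((n, n)) < sparsity
        if drop.all():
            drop.flat[rng.integers(n * n)] = False
        C[drop] = 0.0
        C /= C.sum()
    return ContingencyTable(C=C, n_pairs=n_pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
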