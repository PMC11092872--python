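import numpy as np
import pytest

from prewet.lattice import LatticeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def cube8():
    return LatticeGeometry.cubic(8)


def batch_se(a, n_batches=20):
    """Monte-Carlo standard error from batch means."""
    a = np.asarray(a, dtype=float)
    batches = np.array_split(a, n_batches)
    means = np.array([b.mean() for b in batches])
    return means.std(ddof=1) / np.sqrt(n_batches)
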