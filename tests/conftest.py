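import numpy as np
import pytest
from hypothesis import settings

from hubdisrupt.connectome_io import Connectome

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_connectome():
    """Factory: Connectome from a weight matrix with generated labels."""

    def _make(w, subject_id="s1"):
        w = np.asarray(w, dtype=float)
        labels = [f"region{i:03d}" for i in range(w.shape[0])]
        return Connectome(subject_id, w, labels)

    return _make


@pytest.fixture
def unit_graph(make_connectome):
    """Factory: unit-weight graph from an edge list."""

    def _make(n, edges):
        w = np.zeros((n, n))
        for i, j in edges:
            w[i, j] = w[j, i] = 1.0
        return make_connectome(w)

    return _make
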