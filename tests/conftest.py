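import numpy as np
import pytest

from convphy.trees import make_default_tree


@pytest.fixture(scope="session")
def seq_tree():
    """Default 7-taxon tree on the amino-acid scale used by the
    convergence studies."""
    return make_default_tree("sequence", branch_length=0.05)


@pytest.fixture(scope="session")
def codon_tree():
    """Default 7-taxon tree on the neutral codon scale used by the
    selection studies."""
    return make_default_tree("sequence", branch_length=0.2)


@pytest.fixture(scope="session")
def time_tree():
    return make_default_tree("time")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
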