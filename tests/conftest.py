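import numpy as np
import pytest

from dermocybe import pigments


@pytest.fixture(scope="session")
def reference():
    """Packaged pigment library, 15 species profiles and 4 groups."""
    return pigments.load_reference()


@pytest.fixture(scope="session")
def library(reference):
    return reference[0]


@pytest.fixture(scope="session")
def profiles(reference):
    return reference[1]


@pytest.fixture(scope="session")
def groups(reference):
    return reference[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240405)


def random_distance_matrix(rng, n, labels=None):
    """Random symmetric non-negative matrix with zero diagonal."""
    from dermocybe.congruence import DistanceMatrix

    x = rng.random((n, n))
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 0.0)
    return DistanceMatrix(labels or [f"t{i}" for i in range(n)], x)
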