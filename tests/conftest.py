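import numpy as np
import pytest

from mutsig96.catalog import MutationCatalog, MutationRecord
from mutsig96.scheme import DEFAULT_SCHEME
from mutsig96.synthetic import make_archetypes, simulate_catalog, simulate_exposures


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def archetypes():
    return make_archetypes(leak_fraction=0.05, seed=1)


@pytest.fixture(scope="session")
def clean_archetypes():
    return make_archetypes(leak_fraction=0.0, seed=1)


@pytest.fixture(scope="session")
def tiny_genome():
    # 1-based:      123456789...
    return {"chr1": "TTACGTAGTAACCGGTTACGTACGTTAAGGCCTTAA"}


@pytest.fixture(scope="session")
def small_truth():
    return simulate_exposures(
        30, ["S", "K", "nonCGI", "flat"], (200.0, 0.8), seed=11,
        archetypes=make_archetypes(0.05, seed=1),
    )


@pytest.fixture(scope="session")
def small_catalog(small_truth):
    return simulate_catalog(small_truth, "multinomial", seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
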