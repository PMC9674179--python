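import numpy as np
import pytest

from cglandscape import potentials as pot
from cglandscape import synthetic as syn


@pytest.fixture(scope="session")
def spec():
    return syn.SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def receptor_pair(spec):
    return syn.make_two_domain_receptor(spec)


@pytest.fixture(scope="session")
def open_receptor(receptor_pair):
    return receptor_pair[0]


@pytest.fixture(scope="session")
def closed_receptor(receptor_pair):
    return receptor_pair[1]


@pytest.fixture(scope="session")
def reference_complex(spec):
    return syn.make_reference_complex(spec)


@pytest.fixture(scope="session")
def demo_potential(reference_complex):
    counts = pot.count_atomic_contacts(reference_complex)
    return pot.build_residue_base_potential(reference_complex, counts,
                                            lam=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
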