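"""Shared fixtures: one toy receptor-ligand complex per session."""

import pytest

from pocketforge.core_model import define_pocket
from pocketforge.synthetic import ToyReceptorSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy():
    """(complex, topology, bw_map) for the default toy receptor."""
    return make_toy_complex(ToyReceptorSpec(seed=1))


@pytest.fixture(scope="session")
def toy_complex(toy):
    return toy[0]


@pytest.fixture(scope="session")
def topology(toy):
    return toy[1]


@pytest.fixture(scope="session")
def bw_map(toy):
    return toy[2]


@pytest.fixture(scope="session")
def toy_pocket(toy_complex):
    return define_pocket(toy_complex)
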