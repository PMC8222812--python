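import numpy as np
import pytest

from kirgate import ChannelSpec, SyntheticParams, make_channel, make_ensemble
from kirgate.io_structures import Structure, select


@pytest.fixture(scope="session")
def spec():
    return ChannelSpec()


@pytest.fixture(scope="session")
def params():
    return SyntheticParams()


@pytest.fixture(scope="session")
def open_channel(params, spec):
    """Noise-free fully open tetramer."""
    return make_channel(params, spec)


@pytest.fixture(scope="session")
def reduced_channel(open_channel):
    """Channel region plus margin: small system for dynamics tests."""
    return select(open_channel, residues=(115, 140))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_structure(rng, n_atoms=20, box=10.0):
    """Blob of pseudo-atoms in one residue, for geometry oracles."""
    return Structure(
        ["X"] * n_atoms, ["C"] * n_atoms, [1] * n_atoms, ["ALA"] * n_atoms,
        ["A"] * n_atoms, rng.uniform(0, box, (n_atoms, 3)),
    )
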