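import numpy as np
import pytest

from epsrlite.forcefield import PairPotentialTable
from epsrlite.molecule import build_indomethacin_z
from epsrlite.synth import FixtureSpec, make_motif_configuration, make_open_cluster

# Fixture density: exact motif censuses are only constructible below the
# rigid-random-packing threshold (see docs/methods.md); the analysis
# observables checked here (coordination counts, censuses) do not depend on
# the density by construction.
FIXTURE_DENSITY = 0.050


@pytest.fixture(scope="session")
def template():
    return build_indomethacin_z()


@pytest.fixture(scope="session")
def table():
    return PairPotentialTable()


@pytest.fixture(scope="session")
def dimer_config():
    """64 molecules, all mutual carboxylic-acid dimers at 2.67 A."""
    spec = FixtureSpec(n_molecules=64, density=FIXTURE_DENSITY,
                       composition={"dimer": 1.0}, seed=1)
    return make_motif_configuration(spec)


@pytest.fixture(scope="session")
def isolated_config():
    """64 isolated molecules (no intermolecular hydrogen bonds)."""
    spec = FixtureSpec(n_molecules=64, density=FIXTURE_DENSITY,
                       composition={"isolated": 1.0}, seed=2)
    return make_motif_configuration(spec)


@pytest.fixture(scope="session")
def small_config():
    """A small periodic box for brute-force oracles."""
    spec = FixtureSpec(n_molecules=8, density=FIXTURE_DENSITY,
                       composition={"isolated": 0.5, "dimer": 0.5}, seed=3)
    return make_motif_configuration(spec)


@pytest.fixture(scope="session")
def open_cluster():
    """A compact 8-molecule cluster in a box >= 4x its extent."""
    return make_open_cluster(n_molecules=8, seed=3,
                             composition={"isolated": 0.5, "dimer": 0.5})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
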