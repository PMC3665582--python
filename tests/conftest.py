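import pytest

from structmut import fixtures as fx
from structmut import ramachandran as rama
from structmut.structure_model import read_pdb


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("pdb_fixtures")


@pytest.fixture(scope="session")
def helix_structure(fixture_dir):
    return read_pdb(fx.make_helix(10, fixture_dir / "helix10.pdb"))


@pytest.fixture(scope="session")
def rama_maps():
    """Torsion maps built from a modest synthetic draw (shared; building
    them is the slow part)."""
    return rama.build_maps_from_observations(
        fx.synth_dihedral_sample(20000, seed=1))


@pytest.fixture(scope="session")
def cage_structure(fixture_dir):
    info = fx.make_cage_fixture(fixture_dir / "cage.pdb")
    return read_pdb(info["path"])
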