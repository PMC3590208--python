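import numpy as np
import pytest

from fftdock.molio import build_skin_core, detect_surface_atoms
from fftdock.params import load_params
from fftdock.synthkit import make_pocket_plug


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def pocket_fixture():
    """Pocket-and-plug pair with surfaces detected (shared, read-only)."""
    receptor, ligand, native = make_pocket_plug(seed=7)
    receptor = detect_surface_atoms(receptor)
    ligand = detect_surface_atoms(ligand)
    return receptor, ligand, native


@pytest.fixture(scope="session")
def prepared_pair(pocket_fixture):
    """Pocket fixture with skin/core labels built (improved mode)."""
    receptor, ligand, native = pocket_fixture
    rec, lig = build_skin_core(receptor, ligand, mode="improved")
    return rec, lig, native


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
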