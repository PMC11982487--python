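import numpy as np
import pytest

from shortloop.config import ScreenConfig
from shortloop.fixtures import (
    make_cavity_pocket,
    make_extended_chain,
    make_helix_loop_helix,
    make_hollow_shell,
    make_ideal_helix,
)
from shortloop.screen import screen_model
from shortloop.structure import write_pdb


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def extended10():
    return make_extended_chain(10)


@pytest.fixture(scope="session")
def hlh_nvpays():
    return make_helix_loop_helix(12, "NVPAYS")


@pytest.fixture(scope="session")
def shell5():
    return make_hollow_shell(5.0)


@pytest.fixture(scope="session")
def pocket_model():
    return make_cavity_pocket()


@pytest.fixture(scope="session")
def pocket_result(pocket_model):
    return screen_model(pocket_model, ScreenConfig())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, helix20, hlh_nvpays, pocket_model):
    d = tmp_path_factory.mktemp("pdbs")
    write_pdb(helix20, str(d / "helix.pdb"))
    write_pdb(hlh_nvpays, str(d / "hlh.pdb"))
    write_pdb(pocket_model, str(d / "pocket.pdb"))
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
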