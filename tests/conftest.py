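import numpy as np
import pytest

from spinlabel.synthetic import (make_helix, make_open_site,
                                 make_synthetic_library, make_tight_site)


@pytest.fixture(scope="session")
def helix():
    return make_helix(18)


@pytest.fixture(scope="session")
def backbone(helix):
    res = helix.chain("A").residue(10)
    return {nm: res.atom(nm).pos for nm in ("N", "CA", "CB")}


@pytest.fixture(scope="session")
def open_site():
    return make_open_site(seed=0)


@pytest.fixture(scope="session")
def tight_site():
    return make_tight_site(seed=0)


@pytest.fixture(scope="session")
def library():
    return make_synthetic_library(216, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140529)
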