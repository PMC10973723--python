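import pytest

from mediaopt.design import DesignSpace, block_randomised_layout, latin_hypercube, treatment_map
from mediaopt.synthetic_data import SurfaceSpec, make_landscape


@pytest.fixture(scope="session")
def space() -> DesignSpace:
    return DesignSpace()


@pytest.fixture(scope="session")
def landscape(space):
    return make_landscape(SurfaceSpec(), space=space)


@pytest.fixture()
def small_layout():
    comps = latin_hypercube(7, seed=3)
    return block_randomised_layout(treatment_map(comps), n_blocks=6, seed=1)
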