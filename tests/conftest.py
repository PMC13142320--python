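import numpy as np
import pytest

from fcenrich import Connectome, ReferenceAtlas
from fcenrich.synth import SyntheticSpec, make_atlas, make_geometry

TOY_IDS = ("r1", "r2", "r3", "r4")
TOY_STRUCT = ("cortex_left", "cortex_left", "cortex_right", "cortex_right")
TOY_EDGES = {(0, 1): 0.1, (0, 2): 0.2, (0, 3): 0.3, (1, 2): 0.4, (1, 3): 0.5, (2, 3): 0.6}


@pytest.fixture
def toy_atlas() -> ReferenceAtlas:
    """4-region atlas [1, 2, 3, 4] of the hand-worked example."""
    return ReferenceAtlas("toy", TOY_IDS, [1.0, 2.0, 3.0, 4.0], TOY_STRUCT)


@pytest.fixture
def toy_conn() -> Connectome:
    """4-region connectome with edges e12=.1 ... e34=.6."""
    m = np.zeros((4, 4))
    for (i, j), v in TOY_EDGES.items():
        m[i, j] = m[j, i] = v
    return Connectome(TOY_IDS, m)


@pytest.fixture(scope="session")
def desk_geom():
    """Default desk-scale geometry: 30 parcels per hemisphere + 8 subcortical."""
    return make_geometry(SyntheticSpec())


@pytest.fixture(scope="session")
def desk_atlas(desk_geom):
    return make_atlas(desk_geom, rho=0.5, seed=11, name="desk")


def random_system(rng, n):
    """Random symmetric connectome matrix and tie-free atlas values of size n."""
    a = rng.normal(size=(n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    values = rng.permutation(np.linspace(-1.0, 1.0, n))
    return a, values
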