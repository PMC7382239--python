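import numpy as np
import pytest

import mtconfine as mc


@pytest.fixture
def rect_box():
    """Rectangle domain: 40 x 15 x 15 µm box, long axis +x."""
    return mc.make_domain("box", lx=40, ly=15, lz=15)


@pytest.fixture
def square_box():
    return mc.make_domain("box", lx=20, ly=20, lz=15)


@pytest.fixture
def sphere10():
    return mc.make_domain("sphere", radius=10)


@pytest.fixture
def all_domains(rect_box, square_box, sphere10):
    return [
        rect_box,
        square_box,
        sphere10,
        mc.make_domain("triangular_prism", side=20, height=15),
        mc.make_domain("cylinder", radius=10, height=15),
    ]


def quiet_params(**overrides):
    """Params with every stochastic channel off; tests switch on what
    they probe."""
    base = dict(t_steps=0, p_spont_cat=0.0, p_rescue=0.0, p_cat=0.0,
                p_cross=0.0, k_nuc=0.0, r_replicates=1, seed=0)
    base.update(overrides)
    return mc.SimulationParams(**base)


def seed_mt(state, origin, direction, n_elements=1, **kw):
    """Add an MT of n_elements fixed-length elements growing along
    ``direction`` from ``origin``."""
    ell = 0.2
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    verts = [tuple(np.asarray(origin, float) + i * ell * d)
             for i in range(n_elements + 1)]
    return state.add_mt(verts, tuple(d), **kw)


@pytest.fixture
def quiet():
    return quiet_params
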