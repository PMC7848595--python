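import numpy as np
import pytest

from emcell import Variant, CellType, make_params
from emcell.snapshots import get_steady_state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def torord_endo_ss():
    """Calibrated ToR-ORd+Land endo steady state at 1 Hz (state, mech)."""
    return get_steady_state("torord", "endo", 1000.0, coupled=True)


@pytest.fixture(scope="session")
def ord_endo_ss():
    return get_steady_state("ord", "endo", 1000.0, coupled=True)


@pytest.fixture(scope="session")
def torord_params():
    return make_params(Variant.TORORD, CellType.ENDO)


@pytest.fixture(scope="session")
def ord_params():
    return make_params(Variant.ORD, CellType.ENDO)


def random_ep_states(variant: Variant, rng, n: int):
    """Physiologically plausible random state vectors for oracle checks."""
    from emcell.ep.state import (bootstrap_state, GATE_SLICES, n_states)

    base = bootstrap_state(variant)
    states = []
    for _ in range(n):
        y = base.copy()
        y[0] = rng.uniform(-90.0, 40.0)
        y[1] = rng.uniform(5.0, 15.0)     # nai
        y[2] = y[1] * rng.uniform(0.98, 1.02)
        y[3] = rng.uniform(120.0, 150.0)  # ki
        y[4] = y[3] * rng.uniform(0.999, 1.001)
        y[5] = 10 ** rng.uniform(-5.0, -3.0)   # cai
        y[6] = 10 ** rng.uniform(-5.0, -2.0)   # cass
        y[7] = rng.uniform(0.5, 3.0)      # cansr
        y[8] = rng.uniform(0.5, 3.0)      # cajsr
        g = GATE_SLICES[variant]
        y[g] = rng.uniform(0.0, 1.0, size=g.stop - g.start)
        if variant is Variant.TORORD:
            y[35:40] = rng.dirichlet(np.ones(5))
        n_ep = n_states(variant)
        y[n_ep - 3:n_ep - 1] = rng.uniform(0.0, 0.5, size=2)  # release fluxes
        y[n_ep - 1] = rng.uniform(0.0, 0.1)                   # camk_trap
        states.append(y)
    return states
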