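import numpy as np
import pytest

from lipsss.network import LabelSchedule, ModelParameters, Phase, default_config
from lipsss.model import build_system, simulate


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def system(cfg):
    return build_system(cfg.pools, cfg.transitions)


@pytest.fixture(scope="session")
def params():
    return ModelParameters(j_tca=7.0, j_exch=7.0, t_trans=0.202,
                           p_dil=0.3, p_anap=0.1)


@pytest.fixture(scope="session")
def constant_2c13_schedule():
    """Open-ended [2-13C] acetate infusion (for steady-state checks)."""
    return LabelSchedule((Phase(0.0, 1e6, (("acetate_2_13c", 1.0),)),))


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels(system, cfg, params):
    # trigger numba compilation once per session
    simulate(params, system, cfg.schedule, 0.5)


def random_normalized_state(system, rng):
    y = np.empty(system.n_states)
    for pool in system.pools:
        sl = system.pool_slice(pool.name)
        v = rng.random(sl.stop - sl.start)
        y[sl] = v / v.sum()
    return y
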