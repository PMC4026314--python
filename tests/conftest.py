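import numpy as np
import pytest
from hypothesis import settings

from biolumox.config import CellField, GelGeometry, KineticConfig

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return KineticConfig()


@pytest.fixture(scope="session")
def geometry():
    return GelGeometry()


@pytest.fixture(scope="session")
def cells():
    return CellField()


def rk4_integrate(rhs, y0, t_grid, n_sub=20):
    """Independent fixed-step RK4 integrator used as a reference oracle."""
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = (t1 - t0) / n_sub
        for i in range(n_sub):
            t = t0 + i * h
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
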