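import numpy as np
import pytest

from tonosim.coupling import build_eye, run_simulation
from tonosim.materials import OgdenMaterial
from tonosim.structure import MeridianShell


def make_sphere_shell(n=60, R=10.0, t=0.5, mu=1.0, alpha=2.0):
    """Axisymmetric spherical shell used by the mechanics oracles."""
    th = np.linspace(0.0, np.pi, n + 1)
    r = R * np.sin(th)
    z = R * np.cos(th)
    r[0] = r[-1] = 0.0
    mat = OgdenMaterial(mu=(mu,), alpha=(alpha,))
    return MeridianShell(r, z, np.full(n + 1, t), [mat] * n,
                         equator_index=n // 2)


@pytest.fixture(scope="session")
def default_eye():
    """Stress-free, pre-inflated eye model at the default parameters."""
    return build_eye(iop=15.0)


@pytest.fixture(scope="session")
def coupled_trace(default_eye):
    """One coupled air-puff simulation of the default eye."""
    return run_simulation(default_eye)
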