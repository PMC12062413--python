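import numpy as np
import pytest

from fibroscar.cell_models import MyocyteParams, equilibrate_myocyte
from fibroscar.link_topology import TissueGeometry


@pytest.fixture(scope="session")
def shallow():
    return MyocyteParams.shallow()


@pytest.fixture(scope="session")
def rested_myocyte(shallow):
    """Myocyte equilibrated 2 s from the published initial conditions."""
    return equilibrate_myocyte(shallow)


@pytest.fixture(scope="session")
def small_circle_geom():
    """48x48 lattice with a centred circular scar of radius 0.25 cm."""
    return TissueGeometry.circular_scar(48, r_cm=0.25)


@pytest.fixture(scope="session")
def strip_geom():
    return TissueGeometry.uniform(8, 120)


def synthetic_square_pulse(width_ms, t_end=600.0, dt=0.1, v_rest=-86.0,
                           v_peak=20.0, t_on=100.0):
    """Idealized AP: rectangular pulse with sharp edges."""
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, v_rest)
    v[(t >= t_on) & (t < t_on + width_ms)] = v_peak
    return t, v
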