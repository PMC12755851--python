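import logging

import numpy as np
import pytest

from neuroclass.datatypes import GLIFParams, KernelBasis
from neuroclass.glif_sim import simulate_glif
from neuroclass.stimuli import default_fn_current

logging.getLogger("neuroclass").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def eta_basis():
    return KernelBasis.default()


@pytest.fixture(scope="session")
def adapting_params(eta_basis):
    """A spiking GLIF neuron with non-trivial adaptation and moving threshold."""
    mid = (eta_basis.edges[:-1] + eta_basis.edges[1:]) / 2.0
    return GLIFParams(
        C=150.0, g_L=8.0, E_L=-70.0, V_reset=-60.0, VT_star=-45.0, delta_V=1.0,
        eta_basis=eta_basis, eta_coeffs=30.0 * np.exp(-mid / 150.0),
        gamma_basis=eta_basis, gamma_coeffs=4.0 * np.exp(-mid / 80.0),
        spike_template={"peak": 30.0, "width": 1.0},
    )


@pytest.fixture(scope="session")
def fn_recording(adapting_params):
    """60 s frozen-noise drive at 20 kHz; reused across fitting tests."""
    p = adapting_params
    baseline = p.g_L * (p.VT_star - p.E_L) - 55.0
    current = default_fn_current(250.0, 60_000.0, dt=0.05, baseline=baseline,
                                 target_sd=50.0, n_units=300, seed=11)
    return simulate_glif(p, current, seed=12)
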