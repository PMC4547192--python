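"""Shared fixtures: the reference device and a few expensive solves.

Device solves are session-scoped so every test that needs, say, the
V_REF = 1 V operating point reuses one continuation run.
"""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from biofetsim.device import default_isfet_device
from biofetsim.mesh import build_mesh
from biofetsim.solver import (BiasPoint, DeviceProblem, equilibrium_solve,
                              ramp_to_bias)

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def device10():
    """Reference BioFET: 10 neutral receptor blocks, pH 7."""
    return default_isfet_device(10, 7.0)


@pytest.fixture(scope="session")
def problem10(device10):
    mesh = build_mesh(device10)
    return DeviceProblem(mesh, device10.materials())


@pytest.fixture(scope="session")
def equilibrium10(device10, problem10):
    return equilibrium_solve(problem10.mesh, device10.materials(),
                             problem=problem10)


@pytest.fixture(scope="session")
def state_on(problem10, equilibrium10):
    """Above-threshold operating point V_DS = 0.1 V, V_REF = 1 V."""
    return ramp_to_bias(problem10, BiasPoint(V_drain=0.1, V_ref=1.0),
                        initial=equilibrium10)


@pytest.fixture(scope="session")
def output_curve_on(device10):
    """I_D-V_DS sweep at V_REF = 1 V (above threshold)."""
    from biofetsim.experiments import sweep_id_vds
    grid = np.arange(0.0, 1.01, 0.1)
    return sweep_id_vds(device10, 1.0, grid)


@pytest.fixture(scope="session")
def transfer_curve(device10):
    """I_D-V_REF sweep at V_DS = 0.1 V spanning sub-threshold to on."""
    from biofetsim.experiments import sweep_id_vref
    grid = np.arange(0.3, 1.2001, 0.1)
    return sweep_id_vref(device10, 0.1, grid)


@pytest.fixture(scope="session")
def position_scan(device10):
    """Single-charged-block position scan at the default scan point."""
    from biofetsim.experiments import single_receptor_scan
    return single_receptor_scan(device10, +4.8e-16)
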