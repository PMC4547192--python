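"""Solver verification against closed-form 1D solutions.

Quasi-1D structures built from the same device/mesh machinery: a uniform
silicon resistor (SG flux vs Ohm's law), a MOS capacitor in depletion
(depletion width vs the depletion approximation) and an electrolyte stack
(Nernstian bulk-potential shift per pH unit).
"""

import math

import numpy as np
import pytest

from biofetsim.constants import EPS0_F_CM, Q_E, UM_TO_CM, thermal_voltage
from biofetsim.device import Contact, DeviceSpec, Region, default_isfet_device
from biofetsim.electrolyte import ElectrolyteSpec
from biofetsim.materials import silicon
from biofetsim.mesh import MeshSpec, build_mesh
from biofetsim.solver import (BiasPoint, DeviceProblem, bias_solve,
                              equilibrium_solve, potential_cut, ramp_to_bias)

VT = thermal_voltage(300.0)


def _resistor_device(nd=1e17, length=2.0, depth=0.5):
    regions = (
        Region("body", (0.0, length, -depth, 0.0), "silicon",
               "donor", nd, "uniform"),
        Region("cap_oxide", (0.0, length, 0.0, 0.3), "oxide"),
    )
    contacts = (
        Contact("source", "left", (-depth, 0.0)),
        Contact("drain", "right", (-depth, 0.0)),
        Contact("reference", "top", (0.0, length)),
    )
    return DeviceSpec(regions=regions, receptors=(), contacts=contacts,
                      electrolyte=ElectrolyteSpec())


def test_sg_resistor_matches_ohms_law():
    """Uniform n-type bar: computed current within 0.1% of sigma*A*V/L."""
    nd, length, depth = 1e17, 2.0, 0.5
    dev = _resistor_device(nd, length, depth)
    mesh = build_mesh(dev, MeshSpec(scale=0.7))
    assert mesh.nx >= 15 and mesh.ny >= 10
    mats = dev.materials()
    si = mats["silicon"]
    # bias the top gate exactly at the bar's neutral potential: flat bands,
    # no vertical depletion or accumulation
    v_flat = VT * math.asinh(nd / (2.0 * si.ni))
    prob = DeviceProblem(mesh, mats)
    v = 0.01
    state = bias_solve(mesh, mats, BiasPoint(V_drain=v, V_ref=v_flat),
                       problem=prob)
    n0 = nd / 2.0 + math.sqrt((nd / 2.0) ** 2 + si.ni ** 2)
    p0 = si.ni ** 2 / n0
    sigma = Q_E * (si.mu_n_max * n0 + si.mu_p_max * p0)
    area_per_width = depth * UM_TO_CM            # cm^2 per cm of width
    I_expected = sigma * area_per_width * v / (length * UM_TO_CM) * 1e-4
    I = -state.terminal_currents["drain"]
    assert I == pytest.approx(I_expected, rel=1e-3)


def _mos_device(na=1e16, tox=0.025, depth=1.5):
    regions = (
        Region("body", (0.0, 0.6, -depth, 0.0), "silicon",
               "acceptor", na, "uniform"),
        Region("gate_oxide", (0.0, 0.6, 0.0, tox), "oxide"),
    )
    contacts = (
        Contact("bulk", "bottom", (0.0, 0.6)),
        Contact("reference", "top", (0.0, 0.6)),
    )
    return DeviceSpec(regions=regions, receptors=(), contacts=contacts,
                      electrolyte=ElectrolyteSpec())


def test_mos_depletion_width():
    """Gate-biased MOS capacitor: depletion width within 5% of
    W = sqrt(2 eps_s psi_s / (q N_A))."""
    na = 1e16
    dev = _mos_device(na=na)
    mesh = build_mesh(dev, MeshSpec(scale=0.5))
    mats = dev.materials()
    state = equilibrium_solve(mesh, mats, BiasPoint(V_ref=0.25))
    cut = potential_cut(state, mesh, 0.3)
    y = cut["y_um"].to_numpy()
    sil = y <= 0.0
    psi = cut["psi_V"].to_numpy()[sil]
    p = cut["p_cm3"].to_numpy()[sil]
    ys = y[sil]
    psi_s = psi[np.argmax(ys)] - psi[np.argmin(ys)]   # surface - bulk
    phi_f2 = 2 * VT * math.log(na / mats["silicon"].ni)
    assert 4 * VT < psi_s < phi_f2        # genuinely in depletion
    # measured width: charge-equivalent depletion depth int (1 - p/Na) dy,
    # which removes the Debye-tail ambiguity of a half-density crossing
    order = np.argsort(ys)          # deep bulk -> surface
    ys_o, p_o = ys[order], p[order]
    w_meas = float(np.trapezoid(np.clip(1.0 - p_o / na, 0.0, None), ys_o))
    eps_s = mats["silicon"].eps_r * EPS0_F_CM
    w_theory = math.sqrt(2 * eps_s * psi_s / (Q_E * na)) / UM_TO_CM
    assert w_meas == pytest.approx(w_theory, rel=0.05)


def test_electrolyte_stack_nernst_offset():
    """Bulk electrolyte potential moves by (kT/q) ln10 per pH unit."""
    psis = []
    for ph in (7.0, 8.0):
        dev = default_isfet_device(0, ph)
        mesh = build_mesh(dev)
        state = equilibrium_solve(mesh, dev.materials())
        cut = potential_cut(state, mesh, 3.5)
        bulk = cut[cut["y_um"] > 1.5]["psi_V"].to_numpy()
        psis.append(bulk)
    shift = psis[1] - psis[0]
    nernst = -VT * math.log(10.0)     # higher pH -> lower bulk potential
    assert np.allclose(shift, nernst, atol=5e-4)


def test_potential_cut_contact_endpoint(problem10, equilibrium10):
    """A cut at the device edge ends at the applied bias plus the local
    neutrality offset, and psi is continuous across the stack."""
    mesh = problem10.mesh
    cut = potential_cut(equilibrium10, mesh, float(mesh.x[0]))
    psi_top = cut["psi_V"].to_numpy()[-1]
    # reference electrode grounded, pH 7 -> zero band offset
    assert psi_top == pytest.approx(0.0, abs=1e-9)
    assert np.all(np.isfinite(cut["psi_V"]))
    assert np.max(np.abs(np.diff(cut["psi_V"]))) < 0.3  # no jumps

    with pytest.raises(ValueError):
        potential_cut(equilibrium10, mesh, 1e3)
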