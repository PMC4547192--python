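"""Coupled Poisson / drift-diffusion solver on the tensor-product mesh.

Discretization: finite volumes with Scharfetter-Gummel exponentially fitted
edge fluxes.  The outer iteration is a Gummel loop -- a nonlinear Poisson
solve (damped Newton, Boltzmann densities at frozen quasi-Fermi potentials)
alternating with linear electron and hole continuity solves.  Insulating
regions (oxide, receptor blocks) enter Poisson only; the silicon body and
the electrolyte-equivalent region each form an independent carrier system
(no carrier exchange through the oxide).

Terminal currents are reported in A per um of device width.  Current
extraction uses the quasi-Fermi form of the SG flux,
``J = -coeff * B(d_psi/VT) * c_neighbour * expm1(d_phi/VT)``,
which is algebraically identical to the standard form but free of the
large-term cancellation that otherwise dominates near-equilibrium contact
fluxes.  After Gummel convergence one extra pass re-solves both continuity
equations against a single frozen recombination field, which makes the
discrete contact currents sum to zero up to linear-solver round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import EPS0_F_CM, Q_E, UM_TO_CM, thermal_voltage
from .electrolyte import SemiconductorParams
from .mesh import CARRIER_ELEC, CARRIER_NONE, CARRIER_SI, MAT_IDS, Mesh

__all__ = [
    "bernoulli", "sg_edge_flux", "srh_rate", "surface_mobility",
    "SurfaceMobilityParams", "BiasPoint", "SolverOptions", "SolutionState",
    "NonConvergenceError", "DeviceProblem", "equilibrium_solve",
    "bias_solve", "ramp_to_bias", "potential_cut",
    "LOMBARDI_ELECTRONS", "LOMBARDI_HOLES",
]

_EXP_CLIP = 60.0  # cap on density exponents during Newton transients


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------

def bernoulli(x):
    """Bernoulli function B(x) = x / (exp(x) - 1), elementwise.

    Continuous limit B(0) = 1; satisfies B(x) - B(-x) = -x.  Implemented
    with expm1, accurate to relative 1e-12 everywhere, with asymptotic
    branches for |x| large enough to overflow exp.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    big_pos = x > 500.0
    big_neg = x < -500.0
    mid = ~(big_pos | big_neg)
    zero = x == 0.0
    m = mid & ~zero
    out[m] = x[m] / np.expm1(x[m])
    out[zero] = 1.0
    out[big_pos] = 0.0
    out[big_neg] = -x[big_neg]
    return out[0] if scalar else out


def sg_edge_flux(psi_i, psi_j, c_i, c_j, mu, edge_len, carrier_sign,
                 T: float = 300.0):
    """Scharfetter-Gummel current density along one edge, A/cm^2.

    Current (not particle flux) from node i toward node j per unit edge
    cross-section.  ``carrier_sign`` is the sign of the carrier charge:
    -1 for electrons, +1 for holes.  Densities in cm^-3, ``edge_len`` in
    cm.  Antisymmetric under (i, j) swap; reduces to Fick diffusion
    ``+/- q mu VT (c_j - c_i)/h`` when psi_i == psi_j, and to drift with
    the upwind density for |psi_i - psi_j| >> VT.
    """
    VT = thermal_voltage(T)
    c_i = np.asarray(c_i, float)
    c_j = np.asarray(c_j, float)
    if np.any(c_i <= 0) or np.any(c_j <= 0):
        raise ValueError("carrier densities must be positive")
    s = float(carrier_sign)
    if s not in (-1.0, 1.0):
        raise ValueError("carrier_sign must be +1 or -1")
    d = (np.asarray(psi_j, float) - np.asarray(psi_i, float)) / VT
    coeff = Q_E * mu * VT / edge_len
    return -s * coeff * (bernoulli(-s * d) * c_j - bernoulli(s * d) * c_i)


def srh_rate(n, p, ni, tau_n, tau_p):
    """Shockley-Read-Hall net recombination rate, cm^-3 s^-1.

    Midgap trap level: R = (n p - ni^2) / (tau_p (n + ni) + tau_n (p + ni)).
    Positive for excess carriers, negative (generation) in depletion.
    """
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    if np.any(n <= 0) or np.any(p <= 0) or ni <= 0 or tau_n <= 0 or tau_p <= 0:
        raise ValueError("srh_rate arguments must be positive")
    return (n * p - ni * ni) / (tau_p * (n + ni) + tau_n * (p + ni))


@dataclass(frozen=True)
class SurfaceMobilityParams:
    """Simplified Lombardi surface-mobility coefficients.

    ``1/mu = 1/mu_max + E_perp/B + E_perp^2/delta`` -- acoustic-phonon
    (``mu_ac = B/E_perp``) and surface-roughness (``mu_sr = delta/E^2``)
    terms combined by Matthiessen's rule.  The default coefficients are a
    conventional silicon calibration; they are solver inputs, not measured
    values.  Set ``enabled=False`` (or E_perp = 0) to recover mu_max.
    """

    B: float = 4.75e7        # cm/s
    delta: float = 5.82e14   # V^2 s^-1 cm^-1 scale of the roughness term
    enabled: bool = True


LOMBARDI_ELECTRONS = SurfaceMobilityParams(B=4.75e7, delta=5.82e14)
LOMBARDI_HOLES = SurfaceMobilityParams(B=9.93e6, delta=2.05e14)


def surface_mobility(mu_max, E_perp, params: SurfaceMobilityParams):
    """Field-degraded carrier mobility, cm^2/(V s), elementwise.

    Monotonically non-increasing in the perpendicular field ``E_perp``
    (V/cm); equals ``mu_max`` at zero field or when disabled.
    """
    if np.any(np.asarray(mu_max) <= 0):
        raise ValueError("mu_max must be positive")
    E = np.asarray(E_perp, float)
    if np.any(E < 0):
        raise ValueError("E_perp must be >= 0")
    if not params.enabled:
        return np.broadcast_to(np.asarray(mu_max, float), E.shape).copy() \
            if E.ndim else float(mu_max)
    inv = 1.0 / np.asarray(mu_max, float) + E / params.B + E * E / params.delta
    return 1.0 / inv


# ---------------------------------------------------------------------------
# solver data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasPoint:
    """Applied terminal voltages (V)."""

    V_source: float = 0.0
    V_drain: float = 0.0
    V_bulk: float = 0.0
    V_ref: float = 0.0

    def __post_init__(self) -> None:
        for name in ("V_source", "V_drain", "V_bulk", "V_ref"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def voltage_of(self, contact: str) -> float:
        return {"source": self.V_source, "drain": self.V_drain,
                "bulk": self.V_bulk, "reference": self.V_ref}[contact]

    def is_equilibrium(self) -> bool:
        return (self.V_source == self.V_drain == self.V_bulk == 0.0)


@dataclass(frozen=True)
class SolverOptions:
    gummel_tol_V: float = 1.0e-6
    current_rel_tol: float = 1.0e-5
    max_gummel_iters: int = 200
    newton_damping: float = 1.0
    continuation_step_V: float = 0.05
    current_floor_A_per_um: float = 1.0e-15
    newton_tol_V: float = 1.0e-9
    max_newton_iters: int = 60
    psi_update_clip_V: float = 0.5
    verbose: int = 0

    def __post_init__(self) -> None:
        if self.gummel_tol_V <= 0 or self.current_rel_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_gummel_iters < 1 or self.max_newton_iters < 1:
            raise ValueError("iteration caps must be >= 1")
        if not 0.0 < self.newton_damping <= 1.0:
            raise ValueError("newton_damping must be in (0, 1]")
        if self.continuation_step_V <= 0:
            raise ValueError("continuation_step_V must be positive")


@dataclass
class SolutionState:
    """Converged (or last-iterate) device state at one bias point."""

    psi: np.ndarray          # (ny, nx) V
    n: np.ndarray            # (ny, nx) cm^-3 (0 on non-carrier nodes)
    p: np.ndarray
    phi_n: np.ndarray        # quasi-Fermi potentials, V
    phi_p: np.ndarray
    terminal_currents: dict  # contact -> A per um width
    converged: bool
    iterations: int
    bias: BiasPoint
    residual_history: list = field(default_factory=list)


class NonConvergenceError(RuntimeError):
    """Gummel or Newton iteration failed; carries the last iterate."""

    def __init__(self, message, state=None, history=None):
        super().__init__(
            f"{message} (consider a smaller continuation step); "
            f"residual history: {['%.3e' % r for r in (history or [])][-6:]}")
        self.state = state
        self.history = history or []


# ---------------------------------------------------------------------------
# assembled device problem
# ---------------------------------------------------------------------------

class DeviceProblem:
    """Mesh + materials assembled into solver-ready arrays.

    Built once per (device, mesh); shared across bias points of a sweep.
    """

    def __init__(self, mesh: Mesh, materials: dict[str, SemiconductorParams],
                 lombardi_n: SurfaceMobilityParams = LOMBARDI_ELECTRONS,
                 lombardi_p: SurfaceMobilityParams = LOMBARDI_HOLES):
        self.mesh = mesh
        self.materials = materials
        self.lombardi_n = lombardi_n
        self.lombardi_p = lombardi_p
        si = materials["silicon"]
        el = materials.get("electrolyte")
        self.T = si.T
        self.VT = thermal_voltage(self.T)

        nx, ny = mesh.nx, mesh.ny
        self.nx, self.ny = nx, ny
        self.N = nx * ny
        x_cm, y_cm = mesh.x_cm, mesh.y_cm
        self.hx = np.diff(x_cm)           # (nx-1,)
        self.hy = np.diff(y_cm)           # (ny-1,)

        cm = mesh.cell_mat                # (ny-1, nx-1)
        eps_by_id = np.empty(4)
        for name, mid in MAT_IDS.items():
            m = materials.get(name)
            eps_by_id[mid] = (m.eps_r if m is not None else 1.0) * EPS0_F_CM
        eps_cell = eps_by_id[cm]

        # Poisson edge coefficients (F, i.e. F/cm * cm of section)
        hyh = 0.5 * self.hy
        hxh = 0.5 * self.hx
        Cx = np.zeros((ny, nx - 1))
        Cx[:-1] += eps_cell * hyh[:, None]
        Cx[1:] += eps_cell * hyh[:, None]
        Cx /= self.hx[None, :]
        Cy = np.zeros((ny - 1, nx))
        Cy[:, :-1] += eps_cell * hxh[None, :]
        Cy[:, 1:] += eps_cell * hxh[None, :]
        Cy /= self.hy[:, None]
        self.Cx, self.Cy = Cx, Cy

        # carrier-conduction edge sections per system (cm)
        def _sections(mat_id):
            sel = (cm == mat_id)
            sx = np.zeros((ny, nx - 1))
            sx[:-1] += sel * hyh[:, None]
            sx[1:] += sel * hyh[:, None]
            sy = np.zeros((ny - 1, nx))
            sy[:, :-1] += sel * hxh[None, :]
            sy[:, 1:] += sel * hxh[None, :]
            return sx, sy

        sx_si, sy_si = _sections(MAT_IDS["silicon"])
        sx_el, sy_el = _sections(MAT_IDS["electrolyte"])
        self.sx = sx_si + sx_el           # sections combine: systems disjoint
        self.sy = sy_si + sy_el
        self.edge_sys_x = np.where(sx_si > 0, CARRIER_SI,
                                   np.where(sx_el > 0, CARRIER_ELEC,
                                            CARRIER_NONE))
        self.edge_sys_y = np.where(sy_si > 0, CARRIER_SI,
                                   np.where(sy_el > 0, CARRIER_ELEC,
                                            CARRIER_NONE))

        csys = mesh.carrier_system
        self.carrier = csys
        self.is_carrier = csys != CARRIER_NONE
        self.ni = np.where(csys == CARRIER_SI, si.ni,
                           np.where(csys == CARRIER_ELEC,
                                    el.ni if el else 1.0, 1.0))
        self.beta = np.where(csys == CARRIER_ELEC,
                             el.band_reference if el else 0.0, 0.0)
        self.tau_n = np.where(csys == CARRIER_SI, si.tau_n,
                              el.tau_n if el else si.tau_n)
        self.tau_p = np.where(csys == CARRIER_SI, si.tau_p,
                              el.tau_p if el else si.tau_p)
        self.mu_n_x = np.where(self.edge_sys_x == CARRIER_SI, si.mu_n_max,
                               el.mu_n_max if el else si.mu_n_max)
        self.mu_p_x = np.where(self.edge_sys_x == CARRIER_SI, si.mu_p_max,
                               el.mu_p_max if el else si.mu_p_max)
        self.mu_n_y = np.where(self.edge_sys_y == CARRIER_SI, si.mu_n_max,
                               el.mu_n_max if el else si.mu_n_max)
        self.mu_p_y = np.where(self.edge_sys_y == CARRIER_SI, si.mu_p_max,
                               el.mu_p_max if el else si.mu_p_max)
        self.si_surface_mob = si.surface_mobility

        # carrier-bearing control areas (cm^2) and background charge (C/cm)
        a_si = mesh.area_mat[MAT_IDS["silicon"]]
        a_el = mesh.area_mat[MAT_IDS["electrolyte"]]
        self.area_c = np.where(csys == CARRIER_SI, a_si,
                               np.where(csys == CARRIER_ELEC, a_el, 0.0))
        a_rec = mesh.area_mat[MAT_IDS["receptor_block"]]
        self.q_background = (Q_E * mesh.doping_net * a_si
                             + mesh.fixed_charge_density * a_rec)

        # Dirichlet bookkeeping
        self.contact_masks = mesh.contacts
        self.dirichlet = np.zeros((ny, nx), dtype=bool)
        for mask in mesh.contacts.values():
            self.dirichlet |= mask
        self.free = ~self.dirichlet

        self._build_laplacian()

    # -- assembly helpers --------------------------------------------------
    def _build_laplacian(self):
        """Poisson operator L (CSR): row k of sum_e C_e (psi_nb - psi_k),
        with identity rows at Dirichlet nodes."""
        nx, ny, N = self.nx, self.ny, self.N
        rows, cols, vals = [], [], []

        def add_edges(C, k1, k2):
            free1 = self.free.ravel()[k1]
            free2 = self.free.ravel()[k2]
            rows.extend([k1[free1], k1[free1], k2[free2], k2[free2]])
            cols.extend([k2[free1], k1[free1], k1[free2], k2[free2]])
            vals.extend([C[free1], -C[free1], C[free2], -C[free2]])

        jj, ii = np.meshgrid(np.arange(ny), np.arange(nx - 1), indexing="ij")
        k1 = (jj * nx + ii).ravel()
        add_edges(self.Cx.ravel(), k1, k1 + 1)
        jj, ii = np.meshgrid(np.arange(ny - 1), np.arange(nx), indexing="ij")
        k1 = (jj * nx + ii).ravel()
        add_edges(self.Cy.ravel(), k1, k1 + nx)

        dk = np.flatnonzero(self.dirichlet.ravel())
        rows.append(dk)
        cols.append(dk)
        vals.append(np.ones(dk.size))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        self.L = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))

    # -- boundary values ---------------------------------------------------
    def dirichlet_psi(self, bias: BiasPoint) -> np.ndarray:
        """Dirichlet potential per contact node: applied bias plus the
        local neutrality (band/doping) offset."""
        psi_d = np.zeros((self.ny, self.nx))
        mesh = self.mesh
        for name, mask in self.contact_masks.items():
            V = bias.voltage_of(name)
            carrier = self.is_carrier & mask
            none_c = mask & ~self.is_carrier
            u = np.arcsinh(mesh.doping_net[carrier]
                           / (2.0 * self.ni[carrier]))
            psi_d[carrier] = V + self.beta[carrier] + self.VT * u
            psi_d[none_c] = V
        return psi_d

    def contact_carrier_bc(self, bias: BiasPoint):
        """Equilibrium (charge-neutral) carrier densities and quasi-Fermi
        levels at ohmic contact nodes."""
        n_d = np.zeros((self.ny, self.nx))
        p_d = np.zeros((self.ny, self.nx))
        phi = np.zeros((self.ny, self.nx))
        for name, mask in self.contact_masks.items():
            V = bias.voltage_of(name)
            sel = mask & self.is_carrier
            u = np.arcsinh(self.mesh.doping_net[sel] / (2.0 * self.ni[sel]))
            n_d[sel] = self.ni[sel] * np.exp(u)
            p_d[sel] = self.ni[sel] * np.exp(-u)
            phi[sel] = V
        return n_d, p_d, phi

    # -- Boltzmann densities ----------------------------------------------
    def densities(self, psi, phi_n, phi_p):
        vn = np.clip((psi - self.beta - phi_n) / self.VT,
                     -_EXP_CLIP, _EXP_CLIP)
        vp = np.clip((self.beta + phi_p - psi) / self.VT,
                     -_EXP_CLIP, _EXP_CLIP)
        n = np.where(self.is_carrier, self.ni * np.exp(vn), 0.0)
        p = np.where(self.is_carrier, self.ni * np.exp(vp), 0.0)
        return n, p

    # -- nonlinear Poisson -------------------------------------------------
    def solve_poisson(self, psi0, phi_n, phi_p, psi_d,
                      opts: SolverOptions) -> np.ndarray:
        """Damped Newton on the nonlinear Poisson equation at frozen
        quasi-Fermi potentials.  Returns psi (ny, nx)."""
        ny, nx = self.ny, self.nx
        psi = psi0.copy()
        psi[self.dirichlet] = psi_d[self.dirichlet]
        freef = self.free.ravel()
        dirf = self.dirichlet.ravel()
        b_dir = np.where(dirf, psi_d.ravel(), 0.0)

        def residual(psi_flat):
            p2 = psi_flat.reshape(ny, nx)
            n, p = self.densities(p2, phi_n, phi_p)
            charge = Q_E * (p - n) * self.area_c + self.q_background
            F = self.L @ psi_flat - b_dir
            F[freef] += charge.ravel()[freef]
            return F, n, p

        psi_flat = psi.ravel()
        F, n, p = residual(psi_flat)
        for it in range(opts.max_newton_iters):
            dq = (Q_E * (n + p) * self.area_c / self.VT).ravel()
            dq[dirf] = 0.0
            J = self.L - sp.diags(dq)
            delta = spla.spsolve(J.tocsc(), -F)
            delta *= opts.newton_damping
            np.clip(delta, -opts.psi_update_clip_V, opts.psi_update_clip_V,
                    out=delta)
            step = 1.0
            normF = np.linalg.norm(F)
            for _ in range(6):
                F_new, n_new, p_new = residual(psi_flat + step * delta)
                if np.linalg.norm(F_new) <= normF or normF == 0.0:
                    break
                step *= 0.5
            psi_flat = psi_flat + step * delta
            F, n, p = F_new, n_new, p_new
            if np.max(np.abs(step * delta)) < opts.newton_tol_V:
                return psi_flat.reshape(ny, nx)
        raise NonConvergenceError("nonlinear Poisson Newton did not converge",
                                  history=[float(np.linalg.norm(F))])

    # -- mobility ----------------------------------------------------------
    def edge_mobilities(self, psi):
        """Edge mobilities; Lombardi surface degradation (silicon edges
        only) driven by the local vertical field |E_y|."""
        y = self.mesh.y_cm
        Ey = np.zeros_like(psi)
        Ey[1:-1] = -(psi[2:] - psi[:-2]) / (y[2:] - y[:-2])[:, None]
        Ey[0] = -(psi[1] - psi[0]) / (y[1] - y[0])
        Ey[-1] = -(psi[-1] - psi[-2]) / (y[-1] - y[-2])
        E = np.abs(Ey)
        mu = {"n_x": self.mu_n_x.copy(), "p_x": self.mu_p_x.copy(),
              "n_y": self.mu_n_y.copy(), "p_y": self.mu_p_y.copy()}
        if not self.si_surface_mob:
            return mu
        Ex_edge = 0.5 * (E[:, :-1] + E[:, 1:])
        Ey_edge = 0.5 * (E[:-1, :] + E[1:, :])
        si_x = self.edge_sys_x == CARRIER_SI
        si_y = self.edge_sys_y == CARRIER_SI
        mu["n_x"][si_x] = surface_mobility(self.mu_n_x[si_x], Ex_edge[si_x],
                                           self.lombardi_n)
        mu["p_x"][si_x] = surface_mobility(self.mu_p_x[si_x], Ex_edge[si_x],
                                           self.lombardi_p)
        mu["n_y"][si_y] = surface_mobility(self.mu_n_y[si_y], Ey_edge[si_y],
                                           self.lombardi_n)
        mu["p_y"][si_y] = surface_mobility(self.mu_p_y[si_y], Ey_edge[si_y],
                                           self.lombardi_p)
        return mu

    # -- edge bookkeeping --------------------------------------------------
    def _edges(self, mu, carrier):
        """Per-edge (k1, k2, conductance q*mu*VT*s/h) for carrier edges."""
        nx, ny = self.nx, self.ny
        out = []
        selx = self.edge_sys_x != CARRIER_NONE
        jj, ii = np.nonzero(selx)
        k1 = jj * nx + ii
        cx = (Q_E * (mu["n_x"] if carrier == "n" else mu["p_x"])[selx]
              * self.VT * self.sx[selx] / self.hx[ii])
        out.append((k1, k1 + 1, cx))
        sely = self.edge_sys_y != CARRIER_NONE
        jj, ii = np.nonzero(sely)
        k1 = jj * nx + ii
        cy = (Q_E * (mu["n_y"] if carrier == "n" else mu["p_y"])[sely]
              * self.VT * self.sy[sely] / self.hy[jj])
        out.append((k1, k1 + nx, cy))
        k1 = np.concatenate([o[0] for o in out])
        k2 = np.concatenate([o[1] for o in out])
        g = np.concatenate([o[2] for o in out])
        return k1, k2, g

    def solve_continuity(self, carrier, psi, mu, n_lin, p_lin, fixed_c,
                         solve_mask, R_frozen=None):
        """One linear continuity solve.  ``carrier`` is "n" or "p";
        ``n_lin``/``p_lin`` freeze the SRH linearization; ``R_frozen``
        switches to a fully frozen recombination source.  Nodes outside
        ``solve_mask`` (contacts, and carrier systems that are in exact
        equilibrium) are held at ``fixed_c``."""
        N = self.N
        psi_f = psi.ravel()
        k1, k2, g = self._edges(mu, carrier)
        d = (psi_f[k2] - psi_f[k1]) / self.VT
        Bp = bernoulli(d)      # B(delta)
        Bm = bernoulli(-d)     # B(-delta)

        ni = self.ni
        denom = (self.tau_p * (n_lin + ni) + self.tau_n * (p_lin + ni))
        qA = Q_E * self.area_c
        if R_frozen is None:
            if carrier == "n":
                a = np.where(self.is_carrier, p_lin / denom, 0.0)
            else:
                a = np.where(self.is_carrier, n_lin / denom, 0.0)
            b_src = np.where(self.is_carrier, ni * ni / denom, 0.0)
            rhs_body = (qA * b_src).ravel()
        else:
            a = np.zeros_like(self.ni)
            rhs_body = (-qA * R_frozen).ravel()

        unknown = (solve_mask & ~self.dirichlet).ravel()
        rows, cols, vals = [], [], []
        diag = np.zeros(N)
        rhs = np.zeros(N)

        # edge contributions (M-matrix orientation: positive diagonal)
        if carrier == "n":
            c_self, c_nb = Bm, Bp       # row k1: +g*B(-d) n1 - g*B(d) n2
            c_self2, c_nb2 = Bp, Bm     # row k2 by antisymmetry
        else:
            c_self, c_nb = Bp, Bm
            c_self2, c_nb2 = Bm, Bp
        for (ka, kb, cs, cn) in ((k1, k2, c_self, c_nb),
                                 (k2, k1, c_self2, c_nb2)):
            sel = unknown[ka]
            np.add.at(diag, ka[sel], g[sel] * cs[sel])
            rows.append(ka[sel])
            cols.append(kb[sel])
            vals.append(-g[sel] * cn[sel])

        diag[unknown] += (qA * a).ravel()[unknown]
        rhs[unknown] = rhs_body[unknown]

        fixed = ~unknown
        diag[fixed] = 1.0
        bc = fixed_c.ravel()
        rhs[fixed] = np.where(self.is_carrier.ravel()[fixed], bc[fixed], 0.0)

        rows.append(np.arange(N))
        cols.append(np.arange(N))
        vals.append(diag)
        M = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(N, N))
        c = spla.spsolve(M.tocsc(), rhs)
        c = np.maximum(c, 1e-300)
        c = c.reshape(self.ny, self.nx)
        return np.where(self.is_carrier, c, 0.0)

    # -- current extraction ------------------------------------------------
    def terminal_currents(self, psi, n, p, phi_n, phi_p, mu) -> dict:
        """Contact currents (A per um width), quasi-Fermi SG form."""
        psi_f = psi.ravel()
        nf, pf = n.ravel(), p.ravel()
        dphin = phi_n.ravel()
        dphip = phi_p.ravel()

        k1n, k2n, gn = self._edges(mu, "n")
        k1p, k2p, gp = self._edges(mu, "p")
        dn = (psi_f[k2n] - psi_f[k1n]) / self.VT
        dp = (psi_f[k2p] - psi_f[k1p]) / self.VT
        # J(k1->k2), A/cm of width:
        Jn = -gn * bernoulli(dn) * nf[k2n] * np.expm1(
            np.clip((dphin[k2n] - dphin[k1n]) / self.VT, -700, 700))
        Jp = -gp * bernoulli(dp) * pf[k1p] * np.expm1(
            np.clip((dphip[k2p] - dphip[k1p]) / self.VT, -700, 700))

        out = {}
        for name, mask in self.contact_masks.items():
            m = mask.ravel()
            I = 0.0
            for (k1, k2, J) in ((k1n, k2n, Jn), (k1p, k2p, Jp)):
                into = m[k2] & ~m[k1]
                outof = m[k1] & ~m[k2]
                I += float(np.sum(J[into])) - float(np.sum(J[outof]))
            out[name] = I * 1.0e-4      # A/cm width -> A/um width
        return out


# ---------------------------------------------------------------------------
# high-level solves
# ---------------------------------------------------------------------------

def _system_bias(problem: DeviceProblem, bias: BiasPoint):
    """Per-carrier-system contact voltage; error if a system's contacts
    disagree (then the state is not an equilibrium)."""
    volt = {CARRIER_SI: [], CARRIER_ELEC: []}
    for name, mask in problem.contact_masks.items():
        for sysid in (CARRIER_SI, CARRIER_ELEC):
            if np.any(mask & (problem.carrier == sysid)):
                volt[sysid].append(bias.voltage_of(name))
    out = {}
    for sysid, vs in volt.items():
        if not vs:
            continue
        if max(vs) - min(vs) > 1e-12:
            raise ValueError("equilibrium solve needs equal bias on all "
                             "contacts of each carrier system")
        out[sysid] = vs[0]
    return out


def equilibrium_solve(mesh, materials, bias: BiasPoint | None = None,
                      options: SolverOptions | None = None,
                      problem: DeviceProblem | None = None) -> SolutionState:
    """Thermal-equilibrium solution (zero quasi-Fermi splitting).

    All contacts of a carrier system must share one voltage; insulator
    contacts (e.g. a gate on bare oxide) may sit at any bias.  Densities
    follow the Boltzmann relation exactly, so n*p = ni^2 holds to
    round-off and all terminal currents are identically zero.
    """
    opts = options or SolverOptions()
    prob = problem or DeviceProblem(mesh, materials)
    bias = bias or BiasPoint()
    sysv = _system_bias(prob, bias)

    phi = np.zeros((prob.ny, prob.nx))
    for sysid, v in sysv.items():
        phi[prob.carrier == sysid] = v
    # neutral initial guess
    u = np.arcsinh(np.where(prob.is_carrier,
                            prob.mesh.doping_net / (2.0 * prob.ni), 0.0))
    psi0 = np.where(prob.is_carrier, phi + prob.beta + prob.VT * u, 0.0)
    psi_d = prob.dirichlet_psi(bias)
    psi = prob.solve_poisson(psi0, phi, phi, psi_d, opts)
    n, p = prob.densities(psi, phi, phi)
    currents = {name: 0.0 for name in prob.contact_masks}
    return SolutionState(psi=psi, n=n, p=p, phi_n=phi.copy(),
                         phi_p=phi.copy(), terminal_currents=currents,
                         converged=True, iterations=0, bias=bias)


def bias_solve(mesh, materials, bias: BiasPoint,
               options: SolverOptions | None = None,
               initial: SolutionState | None = None,
               problem: DeviceProblem | None = None) -> SolutionState:
    """Gummel-iterated solution at one bias point.

    ``initial`` should be the equilibrium state or a previously converged
    nearby bias point (use :func:`ramp_to_bias` for large steps).
    """
    opts = options or SolverOptions()
    prob = problem or DeviceProblem(mesh, materials)
    try:
        _system_bias(prob, bias)
        per_system_equilibrium = True
    except ValueError:
        per_system_equilibrium = False
    if per_system_equilibrium:
        # every carrier system sees a single contact voltage: detailed
        # balance holds exactly and all terminal currents are identically
        # zero, so the Gummel loop would only iterate on round-off
        return equilibrium_solve(mesh, materials, bias, opts, prob)
    if initial is None:
        initial = equilibrium_solve(mesh, materials, BiasPoint(), opts, prob)

    # systems whose contacts share one voltage are in exact equilibrium
    # (phi_n = phi_p = V, n p = ni^2, zero current); only systems with a
    # genuine quasi-Fermi split need continuity solves
    sys_volts = {CARRIER_SI: set(), CARRIER_ELEC: set()}
    for name, mask in prob.contact_masks.items():
        for sysid in (CARRIER_SI, CARRIER_ELEC):
            if np.any(mask & (prob.carrier == sysid)):
                sys_volts[sysid].add(bias.voltage_of(name))
    eq_sys = {s: min(v) for s, v in sys_volts.items() if len(v) == 1}
    active = [s for s, v in sys_volts.items() if len(v) > 1]
    solve_mask = np.isin(prob.carrier, active) & prob.is_carrier

    psi = initial.psi.copy()
    phi_n = initial.phi_n.copy()
    phi_p = initial.phi_p.copy()
    psi_d = prob.dirichlet_psi(bias)
    n_bc, p_bc, phi_bc = prob.contact_carrier_bc(bias)
    cmask = prob.dirichlet & prob.is_carrier
    phi_n[cmask] = phi_bc[cmask]
    phi_p[cmask] = phi_bc[cmask]
    for s, v in eq_sys.items():
        m = prob.carrier == s
        phi_n[m] = v
        phi_p[m] = v

    def _update_phi(n, p):
        with np.errstate(divide="ignore"):
            pn = psi - prob.beta - prob.VT * np.log(
                np.maximum(n, 1e-300) / prob.ni)
            pp = psi - prob.beta + prob.VT * np.log(
                np.maximum(p, 1e-300) / prob.ni)
        return (np.where(solve_mask, pn, phi_n),
                np.where(solve_mask, pp, phi_p))

    history = []
    I_prev = None
    n_lin, p_lin = prob.densities(psi, phi_n, phi_p)
    for it in range(1, opts.max_gummel_iters + 1):
        psi_new = prob.solve_poisson(psi, phi_n, phi_p, psi_d, opts)
        dpsi = float(np.max(np.abs(psi_new - psi)))
        psi = psi_new
        mu = prob.edge_mobilities(psi)
        n_eq, p_eq = prob.densities(psi, phi_n, phi_p)
        fixed_n = np.where(cmask, n_bc, n_eq)
        fixed_p = np.where(cmask, p_bc, p_eq)
        n = prob.solve_continuity("n", psi, mu, n_lin, p_lin, fixed_n,
                                  solve_mask)
        p = prob.solve_continuity("p", psi, mu, n_lin, p_lin, fixed_p,
                                  solve_mask)
        phi_n, phi_p = _update_phi(n, p)
        n_lin, p_lin = n, p
        I = prob.terminal_currents(psi, n, p, phi_n, phi_p, mu)
        maxI = max(abs(v) for v in I.values())
        if I_prev is None:
            dI_abs = np.inf
        else:
            dI_abs = max(abs(I[c] - I_prev[c]) for c in I)
        I_prev = I
        history.append(dpsi)
        if opts.verbose:
            print(f"  gummel {it:3d}: dpsi={dpsi:.3e} V, "
                  f"dI={dI_abs / max(maxI, 1e-300):.3e}")
        # mixed criterion: current changes below the contact-flux
        # extraction noise floor carry no information, so the change must
        # only beat rel_tol * I once I is well above that floor
        current_ok = dI_abs < (opts.current_rel_tol * maxI
                               + opts.current_floor_A_per_um)
        if dpsi < opts.gummel_tol_V and current_ok:
            # conservation pass: both continuity solves against one frozen
            # SRH field so contact currents telescope to zero exactly
            ni = prob.ni
            denom = prob.tau_p * (n + ni) + prob.tau_n * (p + ni)
            R = np.where(solve_mask,
                         (n * p - ni * ni) / np.where(denom > 0, denom, 1.0),
                         0.0)
            n = prob.solve_continuity("n", psi, mu, n, p, fixed_n,
                                      solve_mask, R_frozen=R)
            p = prob.solve_continuity("p", psi, mu, n, p, fixed_p,
                                      solve_mask, R_frozen=R)
            phi_n, phi_p = _update_phi(n, p)
            I = prob.terminal_currents(psi, n, p, phi_n, phi_p, mu)
            return SolutionState(psi=psi, n=n, p=p, phi_n=phi_n,
                                 phi_p=phi_p, terminal_currents=I,
                                 converged=True, iterations=it, bias=bias,
                                 residual_history=history)
    state = SolutionState(psi=psi, n=n, p=p, phi_n=phi_n, phi_p=phi_p,
                          terminal_currents=I_prev or {}, converged=False,
                          iterations=opts.max_gummel_iters, bias=bias,
                          residual_history=history)
    raise NonConvergenceError("Gummel iteration did not converge",
                              state=state, history=history)


def ramp_to_bias(problem: DeviceProblem, target: BiasPoint,
                 options: SolverOptions | None = None,
                 initial: SolutionState | None = None) -> SolutionState:
    """Continuation from ``initial`` (default: equilibrium) to ``target``,
    stepping every terminal linearly by at most ``continuation_step_V``;
    the step is halved (twice at most) on non-convergence."""
    opts = options or SolverOptions()
    mesh, mats = problem.mesh, problem.materials
    if initial is None:
        initial = equilibrium_solve(mesh, mats, BiasPoint(), opts, problem)
    b0 = initial.bias
    dv = max(abs(target.V_source - b0.V_source),
             abs(target.V_drain - b0.V_drain),
             abs(target.V_bulk - b0.V_bulk),
             abs(target.V_ref - b0.V_ref))
    nstep = max(1, int(math.ceil(dv / opts.continuation_step_V)))
    state = initial

    def _at(f):
        return BiasPoint(
            V_source=b0.V_source + f * (target.V_source - b0.V_source),
            V_drain=b0.V_drain + f * (target.V_drain - b0.V_drain),
            V_bulk=b0.V_bulk + f * (target.V_bulk - b0.V_bulk),
            V_ref=b0.V_ref + f * (target.V_ref - b0.V_ref))

    f_done, f_step = 0.0, 1.0 / nstep
    halvings = 0
    while f_done < 1.0 - 1e-12:
        f_try = min(1.0, f_done + f_step)
        try:
            state = bias_solve(mesh, mats, _at(f_try), opts,
                               initial=state, problem=problem)
            f_done = f_try
        except NonConvergenceError:
            if halvings >= 2:
                raise
            halvings += 1
            f_step /= 2.0
    return state


def potential_cut(state: SolutionState, mesh: Mesh, x: float):
    """Vertical profile (y, psi, n, p) at lateral position ``x`` (um),
    linearly interpolated between the bracketing mesh columns."""
    import pandas as pd
    if not mesh.x[0] - 1e-9 <= x <= mesh.x[-1] + 1e-9:
        raise ValueError(f"x = {x} um outside the device "
                         f"[{mesh.x[0]}, {mesh.x[-1]}]")
    i = int(np.clip(np.searchsorted(mesh.x, x) - 1, 0, mesh.nx - 2))
    t = (x - mesh.x[i]) / (mesh.x[i + 1] - mesh.x[i])
    t = float(np.clip(t, 0.0, 1.0))

    def interp(f):
        return (1.0 - t) * f[:, i] + t * f[:, i + 1]

    return pd.DataFrame({
        "y_um": mesh.y,
        "psi_V": interp(state.psi),
        "n_cm3": interp(state.n),
        "p_cm3": interp(state.p),
    })
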