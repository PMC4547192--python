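"""Map solution chemistry onto an equivalent intrinsic semiconductor.

The electrolyte region of an ISFET is represented as an intrinsic
semiconductor whose effective densities of states encode the ion
concentrations of the solution: hydronium ions play the role of holes and
hydroxide ions the role of electrons.  With Boltzmann statistics the
Poisson-Boltzmann description of the diffuse double layer is then exactly
the equilibrium semiconductor problem, so the electrolyte can be handed to
the same Poisson/drift-diffusion solver as the silicon body.

The correspondence at a glance (water, pKw = 14, T = 300 K):

* ``p`` = [H3O+] = 10^-pH mol/L * 6.022e20 (mol/L -> cm^-3)
* ``n`` = [OH-]  = 10^-(pKw-pH) mol/L * 6.022e20
* ``NV = p * exp(Eg/2kT)``, ``NC = n * exp(Eg/2kT)`` with the Fermi level
  of the reference (pH 7) material at midgap
* ``ni = sqrt(NC*NV) * exp(-Eg/2kT)`` -- pH independent, = 6.022e13 cm^-3
* pH enters the electrostatics as a rigid band offset
  ``band_reference = (kT/2) ln(NV/NC)``, which moves by exactly
  kT ln10 (~59.5 meV at 300 K) per pH unit: the Nernstian response.

The band gap is a free model parameter, set to 1.5 eV so that Eg/2 is many
thermal energies and the Boltzmann approximation holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    H_PLANCK,
    K_B_EV,
    K_B_J,
    M_E,
    MOL_PER_L_TO_CM3,
    T_DEFAULT,
)


class InvalidParameterError(ValueError):
    """A physical parameter is non-finite or outside its domain."""


class ModelValidityError(ValueError):
    """Inputs violate an assumption of the electrolyte-as-semiconductor map."""


@dataclass(frozen=True)
class ElectrolyteSpec:
    """Solution chemistry and transport inputs for one electrolyte.

    Parameters
    ----------
    pH:
        Solution pH, must lie strictly inside (0, pKw).
    T:
        Temperature in K.
    eps_r:
        Relative permittivity of the solution (78 for water).
    pKw:
        -log10 of the ionic product of water (14 at room temperature).
    mu_cation_max, mu_anion_max:
        Ion mobilities in cm^2/(V s); the defaults reproduce Na+ and Cl-
        drift in a NaCl solution and map onto hole/electron mobility of
        the equivalent material.
    Eg0, alpha, beta:
        Band-gap model ``Eg(T) = Eg0 - alpha*T^2/(T+beta)``.  The
        electrolyte material uses a temperature-independent 1.5 eV gap
        (alpha = 0).
    tau_n, tau_p:
        Shockley-Read-Hall lifetimes (s) used for the generation /
        recombination of the ion pair (water self-ionization analogue).
    """

    pH: float = 7.0
    T: float = T_DEFAULT
    eps_r: float = 78.0
    pKw: float = 14.0
    mu_cation_max: float = 4.98e-4
    mu_anion_max: float = 6.88e-4
    Eg0: float = 1.5
    alpha: float = 0.0
    beta: float = 1.0
    tau_n: float = 1.0e-5
    tau_p: float = 1.0e-5

    def __post_init__(self) -> None:
        for name in ("pH", "T", "eps_r", "pKw", "mu_cation_max",
                     "mu_anion_max", "Eg0", "alpha", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if not 0.0 < self.pH < self.pKw:
            raise InvalidParameterError(
                f"pH must lie in (0, pKw={self.pKw}), got {self.pH}")
        if self.T <= 0:
            raise InvalidParameterError(f"T must be > 0 K, got {self.T}")
        if self.eps_r <= 1:
            raise InvalidParameterError(f"eps_r must exceed 1, got {self.eps_r}")
        if self.mu_cation_max <= 0 or self.mu_anion_max <= 0:
            raise InvalidParameterError("ion mobilities must be positive")
        if self.Eg0 <= 0:
            raise InvalidParameterError(f"Eg0 must be > 0, got {self.Eg0}")


@dataclass(frozen=True)
class SemiconductorParams:
    """Material parameter set consumed by the device solver.

    ``band_reference`` is the offset (eV) of the material's intrinsic level
    from the global reference level: carrier densities in the solver are
    ``n = ni exp((psi - band_reference - phi_n)/VT)`` and symmetrically for
    holes.  For silicon it is 0; for the electrolyte-equivalent material it
    carries the pH signal, ``(kT/2) ln(NV/NC)``.
    """

    name: str
    eps_r: float
    Eg: float
    NC: float
    NV: float
    ni: float
    mu_n_max: float
    mu_p_max: float
    tau_n: float = 1.0e-5
    tau_p: float = 1.0e-5
    band_reference: float = 0.0
    T: float = T_DEFAULT
    has_carriers: bool = True
    surface_mobility: bool = False

    def __post_init__(self) -> None:
        if self.has_carriers:
            if min(self.NC, self.NV, self.ni) <= 0:
                raise InvalidParameterError(
                    f"{self.name}: NC, NV, ni must be positive")
            # mass-action consistency ni^2 = NC*NV*exp(-Eg/kT)
            lhs = 2.0 * math.log(self.ni)
            rhs = (math.log(self.NC) + math.log(self.NV)
                   - self.Eg / (K_B_EV * self.T))
            if abs(lhs - rhs) > 1.0e-10 * max(1.0, abs(rhs)):
                raise InvalidParameterError(
                    f"{self.name}: ni^2 != NC*NV*exp(-Eg/kT) "
                    f"(log mismatch {lhs - rhs:.3e})")


def bandgap_at_T(Eg0: float, alpha: float, beta: float, T: float) -> float:
    """Band gap Eg(T) = Eg0 - alpha*T^2/(T + beta) in eV.

    ``alpha`` (eV/K) and ``beta`` (K) are material-dependent; for alpha >= 0
    the gap shrinks monotonically with temperature from its T = 0 value.
    """
    for name, v in (("Eg0", Eg0), ("alpha", alpha), ("beta", beta), ("T", T)):
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v!r}")
    if T < 0:
        raise InvalidParameterError(f"T must be >= 0, got {T}")
    if beta + T <= 0:
        raise InvalidParameterError(f"beta + T must be > 0, got {beta + T}")
    return Eg0 - alpha * T * T / (T + beta)


def ion_concentrations_from_ph(pH: float, pKw: float = 14.0) -> tuple[float, float]:
    """Hydronium and hydroxide concentrations in cm^-3 for a given pH.

    Returns ``(p, n)`` with p = [H3O+] (the hole analogue) and n = [OH-]
    (the electron analogue).  The product p*n = 10^-pKw * (6.022e20)^2 is
    pH independent -- the ionic-product / mass-action law.
    """
    if not (math.isfinite(pH) and math.isfinite(pKw)):
        raise InvalidParameterError("pH and pKw must be finite")
    if not 0.0 < pH < pKw:
        raise InvalidParameterError(
            f"pH must lie strictly inside (0, {pKw}), got {pH}")
    p = 10.0 ** (-pH) * MOL_PER_L_TO_CM3
    n = 10.0 ** (-(pKw - pH)) * MOL_PER_L_TO_CM3
    return p, n


def dos_from_ph(pH: float, Eg: float, T: float = T_DEFAULT,
                pKw: float = 14.0) -> tuple[float, float]:
    """Effective densities of states (NC, NV) of the electrolyte material.

    The ion concentrations are converted with the Fermi level placed at
    midgap (Ef - EV = EC - Ef = Eg/2), the convention that yields
    NV = NC = 2.4e26 cm^-3 at pH 7 for Eg = 1.5 eV at 300 K:

        NV = p * exp(Eg/2kT),   NC = n * exp(Eg/2kT)

    NC*NV = p*n*exp(Eg/kT) is pH independent at fixed T, Eg, pKw.
    """
    if not (math.isfinite(Eg) and math.isfinite(T)):
        raise InvalidParameterError("Eg and T must be finite")
    if Eg <= 0:
        raise InvalidParameterError(f"Eg must be > 0, got {Eg}")
    if T <= 0:
        raise InvalidParameterError(f"T must be > 0, got {T}")
    p, n = ion_concentrations_from_ph(pH, pKw)
    boltz = math.exp(Eg / (2.0 * K_B_EV * T))
    return n * boltz, p * boltz


def dos_from_effective_mass(m_rel: float, T: float = T_DEFAULT) -> float:
    """Effective DOS 2*(2 pi m* k T / h^2)^(3/2) in cm^-3.

    ``m_rel`` is the density-of-states effective mass in units of the free
    electron mass.  Scales as T^(3/2) and m_rel^(3/2); for m_rel = 1 at
    300 K the familiar 2.51e19 cm^-3.  Inverting this for the electrolyte
    value 2.4e26 cm^-3 shows the implied effective mass of the equivalent
    material (~2e4 m0) -- a bookkeeping device, not a physical carrier.
    """
    if not (math.isfinite(m_rel) and math.isfinite(T)):
        raise InvalidParameterError("m_rel and T must be finite")
    if m_rel <= 0 or T <= 0:
        raise InvalidParameterError("m_rel and T must be positive")
    n_per_m3 = 2.0 * (2.0 * math.pi * m_rel * M_E * K_B_J * T
                      / H_PLANCK ** 2) ** 1.5
    return n_per_m3 * 1.0e-6


def intrinsic_density(NC: float, NV: float, Eg: float,
                      T: float = T_DEFAULT) -> float:
    """Intrinsic carrier density ni = sqrt(NC*NV) exp(-Eg/2kT) in cm^-3."""
    if min(NC, NV, Eg, T) <= 0:
        raise InvalidParameterError("NC, NV, Eg, T must all be positive")
    return math.sqrt(NC * NV) * math.exp(-Eg / (2.0 * K_B_EV * T))


def build_electrolyte_material(spec: ElectrolyteSpec) -> SemiconductorParams:
    """Assemble the full electrolyte-equivalent material from a spec.

    Holes correspond to the cation (hydronium), electrons to the anion
    (hydroxide); the hole mobility is therefore the cation mobility.  The
    band reference (kT/2)*ln(NV/NC) is antisymmetric about pH = pKw/2 and
    advances by kT*ln10 per pH unit, which is what makes the device respond
    Nernstianly.  Raises :class:`ModelValidityError` when the half-gap is
    not at least ten thermal energies (the Boltzmann regime the mapping
    relies on).
    """
    kT = K_B_EV * spec.T
    Eg = bandgap_at_T(spec.Eg0, spec.alpha, spec.beta, spec.T)
    if Eg / 2.0 <= 10.0 * kT:
        raise ModelValidityError(
            f"Eg/2 = {Eg / 2:.3f} eV must exceed 10 kT = {10 * kT:.3f} eV "
            "for the Boltzmann electrolyte mapping to hold")
    NC, NV = dos_from_ph(spec.pH, Eg, spec.T, spec.pKw)
    ni = intrinsic_density(NC, NV, Eg, spec.T)
    band_ref = 0.5 * kT * math.log(NV / NC)
    return SemiconductorParams(
        name=f"electrolyte_pH{spec.pH:g}",
        eps_r=spec.eps_r,
        Eg=Eg,
        NC=NC,
        NV=NV,
        ni=ni,
        mu_n_max=spec.mu_anion_max,
        mu_p_max=spec.mu_cation_max,
        tau_n=spec.tau_n,
        tau_p=spec.tau_p,
        band_reference=band_ref,
        T=spec.T,
        has_carriers=True,
        surface_mobility=False,
    )
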