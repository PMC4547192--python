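"""Physical constants (CODATA 2018) in the unit system used throughout.

Lengths are handled in cm inside the solver (device geometry is entered in
um and converted), energies in eV, potentials in V, carrier and ion
concentrations in cm^-3, currents in A per um of device width.
"""

Q_E = 1.602176634e-19
"""Elementary charge (C)."""

K_B_J = 1.380649e-23
"""Boltzmann constant (J/K)."""

K_B_EV = 8.617333262e-5
"""Boltzmann constant (eV/K)."""

H_PLANCK = 6.62607015e-34
"""Planck constant (J s)."""

M_E = 9.1093837015e-31
"""Free-electron mass (kg)."""

EPS0_F_CM = 8.8541878128e-14
"""Vacuum permittivity (F/cm)."""

N_AVOGADRO = 6.02214076e23
"""Avogadro constant (1/mol)."""

MOL_PER_L_TO_CM3 = 6.022e20
"""Conversion 1 mol/L -> ions/cm^3 (Avogadro / 1000, rounded as is
conventional when quoting ion concentrations to 4 digits)."""

UM_TO_CM = 1.0e-4

T_DEFAULT = 300.0
"""Default lattice/solution temperature (K).

All effective-density-of-states conversions use 300 K: the ionic product of
water K_W = 1e-14 is a 25 C value, but the reference DOS figure for the
electrolyte-equivalent material (2.4e26 cm^-3 at pH 7) is only reproduced
with kT at 300 K, so the whole parameterization is defined at 300 K.
"""


def thermal_voltage(T: float) -> float:
    """kT/q in volts at temperature ``T`` (K)."""
    return K_B_EV * T
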