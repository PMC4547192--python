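"""Built-in material parameter sets: silicon, SiO2, receptor dielectric.

The electrolyte-equivalent material is generated at run time from an
:class:`~biofetsim.electrolyte.ElectrolyteSpec`; everything else is a fixed
room-temperature parameter set.
"""

from __future__ import annotations

from .constants import T_DEFAULT
from .electrolyte import SemiconductorParams, bandgap_at_T, intrinsic_density

SILICON_EG0 = 1.17      # eV at 0 K
SILICON_ALPHA = 4.73e-4  # eV/K
SILICON_BETA = 636.0     # K


def silicon(T: float = T_DEFAULT, tau_n: float = 1.0e-5,
            tau_p: float = 1.0e-5) -> SemiconductorParams:
    """Crystalline silicon with Varshni gap and standard 300 K DOS.

    NC = 2.8e19, NV = 2.65e19 cm^-3 give ni ~ 9.7e9 cm^-3 at 300 K.
    """
    Eg = bandgap_at_T(SILICON_EG0, SILICON_ALPHA, SILICON_BETA, T)
    NC, NV = 2.8e19, 2.65e19
    return SemiconductorParams(
        name="silicon",
        eps_r=11.7,
        Eg=Eg,
        NC=NC,
        NV=NV,
        ni=intrinsic_density(NC, NV, Eg, T),
        mu_n_max=1417.0,
        mu_p_max=470.5,
        tau_n=tau_n,
        tau_p=tau_p,
        band_reference=0.0,
        T=T,
        has_carriers=True,
        surface_mobility=True,
    )


def oxide(T: float = T_DEFAULT) -> SemiconductorParams:
    """SiO2: ideal insulator, Poisson only."""
    return SemiconductorParams(
        name="oxide", eps_r=3.9, Eg=9.0, NC=1.0, NV=1.0, ni=1.0,
        mu_n_max=1.0, mu_p_max=1.0, T=T,
        has_carriers=False, surface_mobility=False)


def receptor_dielectric(eps_r: float = 2.5, T: float = T_DEFAULT) -> SemiconductorParams:
    """Organic receptor-layer block: insulating, may carry fixed charge."""
    return SemiconductorParams(
        name="receptor_block", eps_r=eps_r, Eg=6.0, NC=1.0, NV=1.0, ni=1.0,
        mu_n_max=1.0, mu_p_max=1.0, T=T,
        has_carriers=False, surface_mobility=False)
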