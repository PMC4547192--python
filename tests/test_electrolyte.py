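"""Electrolyte-to-semiconductor parameter mapping."""

import math

import pytest
from hypothesis import given, strategies as st

from biofetsim.constants import K_B_EV, MOL_PER_L_TO_CM3
from biofetsim.electrolyte import (ElectrolyteSpec, InvalidParameterError,
                                   ModelValidityError, SemiconductorParams,
                                   bandgap_at_T, build_electrolyte_material,
                                   dos_from_effective_mass, dos_from_ph,
                                   intrinsic_density,
                                   ion_concentrations_from_ph)


class TestBandgap:
    @pytest.mark.parametrize("args, expected", [
        ((1.5, 0.0, 636.0, 300.0), 1.5),          # alpha = 0: Eg frozen
        ((1.5, 4.73e-4, 636.0, 0.0), 1.5),        # T = 0 limit
        ((1.17, 4.73e-4, 636.0, 300.0), 1.1245),  # silicon at 300 K
    ])
    def test_values(self, args, expected):
        assert bandgap_at_T(*args) == pytest.approx(expected, abs=1e-4)

    def test_never_exceeds_zero_kelvin_gap(self):
        for T in (1.0, 77.0, 300.0, 500.0):
            assert bandgap_at_T(1.17, 4.73e-4, 636.0, T) <= 1.17

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidParameterError):
            bandgap_at_T(float("nan"), 0.0, 1.0, 300.0)
        with pytest.raises(InvalidParameterError):
            bandgap_at_T(1.5, 0.0, -400.0, 300.0)  # beta + T <= 0


class TestIonConcentrations:
    def test_neutral_water(self):
        p, n = ion_concentrations_from_ph(7.0, 14.0)
        assert p == pytest.approx(6.022e13, rel=1e-12)
        assert n == p  # neutral-point symmetry

    def test_acidic(self):
        p, n = ion_concentrations_from_ph(4.0, 14.0)
        assert p == pytest.approx(6.022e16, rel=1e-12)
        assert n == pytest.approx(6.022e10, rel=1e-12)

    @given(st.floats(0.5, 13.5))
    def test_ionic_product_conserved(self, ph):
        p, n = ion_concentrations_from_ph(ph, 14.0)
        kw = 1e-14 * MOL_PER_L_TO_CM3 ** 2
        assert p * n == pytest.approx(kw, rel=1e-12)

    @pytest.mark.parametrize("ph", [0.0, 14.0, -1.0, 15.0])
    def test_domain(self, ph):
        with pytest.raises(InvalidParameterError):
            ion_concentrations_from_ph(ph, 14.0)


class TestDensityOfStates:
    def test_ph7_reproduces_published_value(self):
        NC, NV = dos_from_ph(7.0, 1.5, 300.0)
        assert NV == pytest.approx(2.4e26, rel=0.02)
        assert NC == NV

    def test_nc_nv_product_ph_independent(self):
        ref = math.prod(dos_from_ph(7.0, 1.5, 300.0))
        for ph in (4.0, 5.5, 10.0):
            assert math.prod(dos_from_ph(ph, 1.5, 300.0)) == \
                pytest.approx(ref, rel=1e-10)

    def test_effective_mass_form(self):
        assert dos_from_effective_mass(1.0, 300.0) == \
            pytest.approx(2.51e19, rel=1e-3)
        # T^(3/2) scaling
        assert dos_from_effective_mass(1.0, 1200.0) == \
            pytest.approx(8 * dos_from_effective_mass(1.0, 300.0), rel=1e-12)

    def test_implied_electrolyte_effective_mass(self):
        # invert the closed form for the electrolyte DOS value
        target = dos_from_ph(7.0, 1.5, 300.0)[1]
        m_rel = (target / dos_from_effective_mass(1.0, 300.0)) ** (2.0 / 3.0)
        assert dos_from_effective_mass(m_rel, 300.0) == \
            pytest.approx(target, rel=1e-9)
        assert m_rel > 1e4  # far heavier than a real carrier


class TestIntrinsicDensity:
    def test_matches_ion_concentration_at_ph7(self):
        NC, NV = dos_from_ph(7.0, 1.5, 300.0)
        p, n = ion_concentrations_from_ph(7.0, 14.0)
        assert intrinsic_density(NC, NV, 1.5, 300.0) == \
            pytest.approx(math.sqrt(p * n), rel=1e-9)

    def test_vanishing_gap_limit(self):
        assert intrinsic_density(4e19, 9e19, 1e-12, 300.0) == \
            pytest.approx(6e19, rel=1e-9)

    def test_ph_independent(self):
        vals = []
        for ph in (4.0, 7.0, 10.0):
            NC, NV = dos_from_ph(ph, 1.5, 300.0)
            vals.append(intrinsic_density(NC, NV, 1.5, 300.0))
        assert max(vals) == pytest.approx(min(vals), rel=1e-10)


class TestBuildMaterial:
    def test_default_water(self):
        m = build_electrolyte_material(ElectrolyteSpec())
        assert m.NC == pytest.approx(2.4e26, rel=0.02)
        assert m.NV == m.NC
        assert m.mu_p_max == 4.98e-4    # cation (hydronium <-> hole)
        assert m.mu_n_max == 6.88e-4    # anion
        assert m.eps_r == 78.0
        assert m.band_reference == 0.0  # intrinsic level at midgap

    def test_mass_action_invariant(self):
        for ph in (3.0, 7.0, 11.0):
            m = build_electrolyte_material(ElectrolyteSpec(pH=ph))
            rhs = m.NC * m.NV * math.exp(-m.Eg / (K_B_EV * m.T))
            assert m.ni ** 2 == pytest.approx(rhs, rel=1e-10)

    def test_band_reference_antisymmetry(self):
        m6 = build_electrolyte_material(ElectrolyteSpec(pH=6.0))
        m8 = build_electrolyte_material(ElectrolyteSpec(pH=8.0))
        assert m6.band_reference == pytest.approx(-m8.band_reference,
                                                  rel=1e-12)

    def test_nernstian_band_shift(self):
        kT_ln10 = K_B_EV * 300.0 * math.log(10.0)
        prev = build_electrolyte_material(ElectrolyteSpec(pH=4.0))
        for ph in (5.0, 6.0, 7.0, 8.0):
            cur = build_electrolyte_material(ElectrolyteSpec(pH=ph))
            shift = prev.band_reference - cur.band_reference
            assert shift == pytest.approx(kT_ln10, rel=1e-12)
            prev = cur

    def test_boltzmann_validity_guard(self):
        with pytest.raises(ModelValidityError):
            build_electrolyte_material(ElectrolyteSpec(Eg0=0.4))

    def test_invalid_spec(self):
        with pytest.raises(InvalidParameterError):
            ElectrolyteSpec(pH=15.0)
        with pytest.raises(InvalidParameterError):
            ElectrolyteSpec(eps_r=0.5)
        with pytest.raises(InvalidParameterError):
            ElectrolyteSpec(mu_cation_max=-1.0)

    def test_params_consistency_check(self):
        with pytest.raises(InvalidParameterError):
            SemiconductorParams(name="bad", eps_r=10, Eg=1.0, NC=1e19,
                                NV=1e19, ni=1e15, mu_n_max=1, mu_p_max=1)
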