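"""Experiment drivers: sweeps, threshold extraction, occupancy sampling."""

import math

import numpy as np
import pandas as pd
import pytest

from biofetsim.experiments import (DEFAULT_I_CRIT, ExtractionError, IVCurve,
                                   OccupancyStudyResult, channel_profile,
                                   extract_threshold, modulation_ratio,
                                   sample_patterns)
from biofetsim.solver import BiasPoint


def _exp_curve(v0, vt, slope_mv=80.0, i0=1e-7):
    V = np.arange(v0, v0 + 1.0001, 0.05)
    I = i0 * 10.0 ** ((V - vt) / (slope_mv / 1000.0))
    return IVCurve("ref", V, I, BiasPoint(V_drain=2.0), 7.0)


class TestExtractThreshold:
    def test_recovers_exponential_threshold(self):
        curve = _exp_curve(0.0, 0.4321)
        assert extract_threshold(curve, 1e-7) == pytest.approx(0.4321,
                                                               abs=1e-6)

    def test_translation_invariance(self):
        for dv in (-0.2, 0.13):
            a = extract_threshold(_exp_curve(0.0, 0.5), 1e-8)
            b = extract_threshold(_exp_curve(0.0 + dv, 0.5 + dv), 1e-8)
            assert b - a == pytest.approx(dv, abs=1e-9)

    def test_exact_sample_point(self):
        curve = _exp_curve(0.0, 0.5)
        i_at_sample = float(np.abs(curve.I_D[4]))
        assert extract_threshold(curve, i_at_sample) == \
            pytest.approx(curve.bias_values[4], abs=1e-12)

    def test_no_crossing(self):
        with pytest.raises(ExtractionError):
            extract_threshold(_exp_curve(0.0, 0.5), 1e3)

    def test_default_criterion_scaling(self):
        # 1e-7 A/um scaled by W/L = 1/5
        assert DEFAULT_I_CRIT == pytest.approx(2e-8)


class TestIVCurve:
    def test_rejects_nonmonotone(self):
        with pytest.raises(ValueError):
            IVCurve("drain", np.array([0.0, 0.2, 0.1]), np.zeros(3),
                    BiasPoint(), 7.0)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            IVCurve("drain", np.arange(3.0), np.zeros(4), BiasPoint(), 7.0)

    def test_frame_roundtrip(self):
        c = _exp_curve(0.0, 0.5)
        df = c.to_frame()
        assert np.array_equal(df["I_D_A_per_um"].to_numpy(), c.I_D)


class TestSamplePatterns:
    def test_single_combination(self):
        assert sample_patterns(10, 10, 99, seed=3) == \
            [tuple(range(1, 11))]

    def test_baseline_only(self):
        assert sample_patterns(10, 0, 5, seed=0) == [()]

    def test_deterministic_in_seed(self):
        a = sample_patterns(10, 3, 7, seed=42)
        b = sample_patterns(10, 3, 7, seed=42)
        c = sample_patterns(10, 3, 7, seed=43)
        assert a == b
        assert a != c

    def test_distinct_and_uniform_support(self):
        pats = sample_patterns(10, 2, 45, seed=1)
        assert len(pats) == 45                      # all C(10,2)
        assert len(set(pats)) == 45

    def test_bounds(self):
        with pytest.raises(ValueError):
            sample_patterns(10, 11, 1, seed=0)
        with pytest.raises(ValueError):
            sample_patterns(10, 3, 0, seed=0)


class TestModulationRatio:
    def _fam(self, i_off, i_on, n=10):
        op = BiasPoint(V_drain=0.1)
        return [
            OccupancyStudyResult(0, [()], [i_off], op),
            OccupancyStudyResult(n, [tuple(range(1, n + 1))], [i_on], op),
        ]

    def test_identical_currents(self):
        assert modulation_ratio(self._fam(3e-9, 3e-9)) == 1.0

    def test_scale_invariance(self):
        r1 = modulation_ratio(self._fam(1e-12, 4e-8))
        r2 = modulation_ratio(self._fam(1e-6, 4e-2))
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_missing_baseline(self):
        op = BiasPoint()
        fam = [OccupancyStudyResult(10, [tuple(range(1, 11))], [1e-8], op)]
        with pytest.raises(ValueError):
            modulation_ratio(fam)

    def test_zero_baseline(self):
        with pytest.raises(ZeroDivisionError):
            modulation_ratio(self._fam(0.0, 1e-8))


class TestRandomCombinations:
    def test_all_on_study_is_deterministic(self, device10):
        from biofetsim.experiments import random_combinations
        from biofetsim.solver import BiasPoint
        op = BiasPoint(V_drain=0.1, V_ref=1.0)
        res = random_combinations(device10, 10, 3, seed=5, operating=op)
        assert res.patterns == [tuple(range(1, 11))]  # single combination
        assert len(res.I_D_at_operating_point) == 1
        assert res.I_D_at_operating_point[0] > 1e-8   # strongly turned on


class TestChannelProfile:
    def test_positive_and_shaped(self, problem10, equilibrium10):
        prof = channel_profile(equilibrium10, problem10.mesh, depth=0.002)
        assert len(prof) == problem10.mesh.nx
        assert np.all(prof["n_cm3"] > 0)

    def test_symmetric_at_equilibrium(self, problem10, equilibrium10):
        """Symmetric device, V_DS = 0: profile symmetric about mid-channel."""
        prof = channel_profile(equilibrium10, problem10.mesh, depth=0.002)
        x = prof["x_um"].to_numpy()
        logn = np.log10(prof["n_cm3"].to_numpy())
        mirrored = np.interp(7.0 - x, x, logn)
        assert np.max(np.abs(logn - mirrored)) < 0.05  # dex

    def test_depth_domain(self, problem10, equilibrium10):
        with pytest.raises(ValueError):
            channel_profile(equilibrium10, problem10.mesh, depth=5.0)
        with pytest.raises(ValueError):
            channel_profile(equilibrium10, problem10.mesh, depth=-0.1)


class TestSweepShapes:
    def test_output_characteristic_saturates(self, output_curve_on):
        """MOSFET-like output curve: zero at V_DS = 0, monotone rise,
        clear saturation at the end of the sweep."""
        I = output_curve_on.I_D
        V = output_curve_on.bias_values
        assert abs(I[0]) < 1e-18
        assert np.all(np.diff(I) > -1e-18)
        g_first = (I[1] - I[0]) / (V[1] - V[0])  # deep linear regime
        g_last = (I[-1] - I[-2]) / (V[-1] - V[-2])
        assert g_last < 0.1 * g_first

    def test_transfer_curve_monotone_and_exponential(self, transfer_curve):
        """I_D grows monotonically with V_REF; sub-threshold region is
        exponential with slope >= 60 mV/decade."""
        I = np.abs(transfer_curve.I_D)
        V = transfer_curve.bias_values
        assert np.all(np.diff(I) > 0)
        sub = I < 1e-10
        logI = np.log10(I[sub])
        dec_per_V = np.diff(logI) / np.diff(V[sub])
        slopes_mv_per_dec = 1000.0 / dec_per_V
        assert np.all(slopes_mv_per_dec >= 59.9)

    def test_vref_curves_ordered(self, output_curve_on, device10):
        """The V_REF = 1 V output curve lies above the V_REF = 0 V one."""
        from biofetsim.experiments import sweep_id_vds
        low = sweep_id_vds(device10, 0.0, np.array([0.0, 0.1, 0.2]))
        hi = output_curve_on
        for v, i_low in zip(low.bias_values[1:], low.I_D[1:]):
            i_hi = np.interp(v, hi.bias_values, hi.I_D)
            assert i_hi > abs(i_low) * 10
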