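"""Acid-base chemistry: charge-balance pH, gas transfer and outflow."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stf
from scipy.optimize import bisect

from admsplit.chemistry import (EquilibriumConstants, charge_balance,
                                gas_outflow, normalise_gas_flow, solve_ph)

T37 = 310.15


def totals(**kw):
    base = {"S_IC": 0.0, "S_IN": 0.0, "S_cat": 0.0, "S_an": 0.0,
            "S_ac": 0.0, "S_pro": 0.0, "S_bu": 0.0, "S_va": 0.0}
    base.update(kw)
    return base


class TestSolvePh:
    def test_pure_water_at_25C_is_neutral(self):
        eq = EquilibriumConstants.at_temperature(298.15)
        spec = solve_ph(totals(), eq)
        assert spec.pH == pytest.approx(7.0, abs=1e-6)

    def test_balanced_strong_ions_stay_neutral(self):
        eq = EquilibriumConstants.at_temperature(298.15)
        spec = solve_ph(totals(S_cat=0.05, S_an=0.05), eq)
        assert spec.pH == pytest.approx(7.0, abs=1e-6)

    def test_bicarbonate_buffer_matches_brute_force_bisection(self):
        """Independent oracle: plain bisection on the same charge balance."""
        eq = EquilibriumConstants.at_temperature(T37)
        tot = totals(S_IC=0.10, S_cat=0.08, S_an=0.02)
        spec = solve_ph(tot, eq)
        H_ref = bisect(charge_balance, 1e-14, 1.0, args=(tot, eq),
                       xtol=1e-30, rtol=8.9e-16, maxiter=500)
        assert spec.pH == pytest.approx(-math.log10(H_ref), abs=1e-10)
        # residual at the root is numerically zero
        assert abs(charge_balance(spec.H, tot, eq)) < 1e-12

    def test_vfa_acidifies(self):
        eq = EquilibriumConstants.at_temperature(T37)
        neutral = solve_ph(totals(S_IC=0.1, S_cat=0.1), eq)
        acid = solve_ph(totals(S_IC=0.1, S_cat=0.1, S_ac=5.0, S_bu=5.0), eq)
        assert acid.pH < neutral.pH - 0.5

    @given(S_IC=stf.floats(0, 0.3), S_IN=stf.floats(0, 0.1),
           S_cat=stf.floats(0, 0.2), S_an=stf.floats(0, 0.2),
           S_ac=stf.floats(0, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_unique_root_and_speciation_consistency(self, S_IC, S_IN, S_cat,
                                                    S_an, S_ac):
        """Charge balance is monotone in [H+]: the solver's root is unique
        and agrees with bracketed bisection to 1e-10 pH units."""
        eq = EquilibriumConstants.at_temperature(T37)
        tot = totals(S_IC=S_IC, S_IN=S_IN, S_cat=S_cat, S_an=S_an, S_ac=S_ac)
        spec = solve_ph(tot, eq)
        H_ref = bisect(charge_balance, 1e-14, 1.0, args=(tot, eq),
                       xtol=1e-30, rtol=8.9e-16, maxiter=500)
        assert spec.pH == pytest.approx(-math.log10(H_ref), abs=1e-10)
        assert spec.co2_aq + spec.hco3 == pytest.approx(S_IC, rel=1e-9, abs=1e-15)
        assert spec.nh3 + spec.nh4 == pytest.approx(S_IN, rel=1e-9, abs=1e-15)

    def test_warm_start_does_not_change_the_root(self):
        eq = EquilibriumConstants.at_temperature(T37)
        tot = totals(S_IC=0.11, S_IN=0.05, S_cat=0.0783, S_an=0.0198, S_ac=0.3)
        cold = solve_ph(tot, eq)
        warm = solve_ph(tot, eq, H_guess=1e-5)
        assert warm.pH == pytest.approx(cold.pH, abs=1e-10)


class TestGasOutflow:
    def test_no_overpressure_no_flow(self):
        assert gas_outflow(1.01325, k_p=5e4) == 0.0

    def test_small_overpressure_linearises(self):
        eps = 1e-6
        q = gas_outflow(1.01325 + eps, k_p=5e4)
        assert q == pytest.approx(5e4 * eps, rel=1e-4)

    def test_flow_scales_with_kp(self):
        q1 = gas_outflow(1.05, k_p=1e4)
        q2 = gas_outflow(1.05, k_p=2e4)
        assert q2 == pytest.approx(2 * q1)

    def test_norm_conversion(self):
        # 1 L at 310.15 K and 1.013 bar shrinks to 273.15/310.15 L at norm T
        q = normalise_gas_flow(1.0, T=310.15, P=1.01325)
        assert q == pytest.approx(273.15 / 310.15)

    def test_rejects_nonpositive_pressure(self):
        with pytest.raises(ValueError):
            gas_outflow(0.0, k_p=1e4)


class TestEquilibriumConstants:
    def test_constants_shift_with_temperature(self):
        eq25 = EquilibriumConstants.at_temperature(298.15)
        eq37 = EquilibriumConstants.at_temperature(T37)
        assert eq37.K_w > eq25.K_w                 # endothermic
        assert eq37.K_H_co2 < eq25.K_H_co2         # gases less soluble warm
        assert eq37.p_h2o > eq25.p_h2o
        assert eq37.p_h2o == pytest.approx(0.062, abs=0.003)
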