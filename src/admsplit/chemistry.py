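"""Acid-base speciation, charge-balance pH solve, Henry constants.

The liquid phase is treated as an instantaneous acid-base equilibrium: at
every right-hand-side evaluation the proton concentration is the root of
the charge balance

    S_cat + NH4+ + H+ - HCO3- - (VFA anions) - OH- - S_an = 0   (eq/L)

which is strictly monotone in [H+] and therefore has a unique solution.
Dissociation constants for the carbonate and ammonium systems and the water
autoionisation are van't-Hoff-corrected to the operating temperature; the
VFA constants are taken as temperature independent, as in the ADM1 report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

R_GAS = 8.314          # J/mol/K
R_BAR = 0.083145       # bar*L/mol/K
T_REF = 298.15
P_NORM = 1.01325       # bar
T_NORM = 273.15        # K

# gCOD per mol for the gas species (CO2 carries none)
COD_PER_MOL_H2 = 16.0
COD_PER_MOL_CH4 = 64.0

# VFA acid dissociation constants (25 degC, assumed T-independent)
KA_AC = 10.0 ** -4.76
KA_PRO = 10.0 ** -4.88
KA_BU = 10.0 ** -4.82
KA_VA = 10.0 ** -4.86

# gCOD per mol of the undissociated acids (charge-equivalent weights)
COD_EQ_AC, COD_EQ_PRO, COD_EQ_BU, COD_EQ_VA = 64.0, 112.0, 160.0, 208.0


def _vant_hoff(k_ref: float, delta_h: float, T: float) -> float:
    return k_ref * math.exp(delta_h / R_GAS * (1.0 / T_REF - 1.0 / T))


@dataclass(frozen=True)
class EquilibriumConstants:
    """Temperature-corrected equilibrium and Henry constants."""

    T: float
    K_w: float
    K_a_co2: float
    K_a_in: float
    K_H_co2: float   # M/bar
    K_H_ch4: float   # M/bar
    K_H_h2: float    # M/bar
    p_h2o: float     # bar

    @classmethod
    def at_temperature(cls, T: float) -> "EquilibriumConstants":
        return cls(
            T=T,
            K_w=_vant_hoff(1.0e-14, 55900.0, T),
            K_a_co2=_vant_hoff(10.0 ** -6.35, 7646.0, T),
            K_a_in=_vant_hoff(10.0 ** -9.25, 51965.0, T),
            K_H_co2=_vant_hoff(0.035, -19410.0, T),
            K_H_ch4=_vant_hoff(0.0014, -14240.0, T),
            K_H_h2=_vant_hoff(7.8e-4, -4180.0, T),
            p_h2o=0.0313 * math.exp(5290.0 * (1.0 / T_REF - 1.0 / T)),
        )


@dataclass(frozen=True)
class Speciation:
    """Full acid-base speciation at the charge-balance root."""

    pH: float
    H: float
    co2_aq: float    # dissolved CO2 (M)
    hco3: float      # bicarbonate (M)
    nh3: float       # free ammonia (M)
    nh4: float       # ammonium (M)
    ac_anion: float  # acetate anion (M)
    pro_anion: float
    bu_anion: float
    va_anion: float


def charge_balance(H: float, totals: dict, eq: EquilibriumConstants) -> float:
    """Net charge (eq/L) at proton concentration ``H``; increasing in H."""
    nh4 = totals["S_IN"] * H / (H + eq.K_a_in)
    hco3 = totals["S_IC"] * eq.K_a_co2 / (H + eq.K_a_co2)
    vfa = (totals["S_ac"] / COD_EQ_AC * KA_AC / (KA_AC + H)
           + totals["S_pro"] / COD_EQ_PRO * KA_PRO / (KA_PRO + H)
           + totals["S_bu"] / COD_EQ_BU * KA_BU / (KA_BU + H)
           + totals["S_va"] / COD_EQ_VA * KA_VA / (KA_VA + H))
    return totals["S_cat"] + nh4 + H - hco3 - vfa - eq.K_w / H - totals["S_an"]


def solve_ph(totals: dict, eq: EquilibriumConstants,
             H_guess: float | None = None, tol: float = 1.0e-14) -> Speciation:
    """Solve the charge balance for pH and return the full speciation.

    ``totals`` holds non-negative lump concentrations: S_IC, S_IN, S_cat,
    S_an (M) and the total VFA pools S_ac, S_pro, S_bu, S_va (gCOD/L).
    Newton iteration from ``H_guess`` (warm start) with a bracketed
    bisection fallback on [pH 0, pH 14].  The default tolerance (1e-14
    eq/L, well inside the 1e-12 contract) keeps the pH accurate to ~1e-12
    units even for weakly buffered compositions.
    """
    totals = {k: max(v, 0.0) for k, v in totals.items()}

    def f_and_df(H: float) -> tuple[float, float]:
        nh4 = totals["S_IN"] * H / (H + eq.K_a_in)
        d_nh4 = totals["S_IN"] * eq.K_a_in / (H + eq.K_a_in) ** 2
        hco3 = totals["S_IC"] * eq.K_a_co2 / (H + eq.K_a_co2)
        d_hco3 = -totals["S_IC"] * eq.K_a_co2 / (H + eq.K_a_co2) ** 2
        f = totals["S_cat"] + nh4 + H - hco3 - eq.K_w / H - totals["S_an"]
        df = d_nh4 + 1.0 - d_hco3 + eq.K_w / H ** 2
        for tot, w, ka in ((totals["S_ac"], COD_EQ_AC, KA_AC),
                           (totals["S_pro"], COD_EQ_PRO, KA_PRO),
                           (totals["S_bu"], COD_EQ_BU, KA_BU),
                           (totals["S_va"], COD_EQ_VA, KA_VA)):
            an = tot / w * ka / (ka + H)
            f -= an
            df += tot / w * ka / (ka + H) ** 2
        return f, df

    H = H_guess if H_guess and 1e-14 < H_guess < 1.0 else 1e-7
    converged = False
    for _ in range(60):
        f, df = f_and_df(H)
        if abs(f) < tol:
            converged = True
            break
        step = f / df
        H_new = H - step
        if H_new <= 0.0:
            H_new = H / 10.0 if f > 0 else H * 10.0  # keep positive, move downhill
        H = min(max(H_new, 1e-15), 10.0)
    if not converged:
        f_lo = charge_balance(1e-14, totals, eq)
        f_hi = charge_balance(1.0, totals, eq)
        if f_lo * f_hi > 0.0:
            raise ArithmeticError(
                "charge balance has no root in [pH 0, pH 14]; "
                f"impossible ionic composition: {totals}")
        H = brentq(charge_balance, 1e-14, 1.0, args=(totals, eq),
                   xtol=1e-16, rtol=8.9e-16, maxiter=200)

    nh4 = totals["S_IN"] * H / (H + eq.K_a_in)
    hco3 = totals["S_IC"] * eq.K_a_co2 / (H + eq.K_a_co2)
    return Speciation(
        pH=-math.log10(H), H=H,
        co2_aq=totals["S_IC"] - hco3, hco3=hco3,
        nh3=totals["S_IN"] - nh4, nh4=nh4,
        ac_anion=totals["S_ac"] / COD_EQ_AC * KA_AC / (KA_AC + H),
        pro_anion=totals["S_pro"] / COD_EQ_PRO * KA_PRO / (KA_PRO + H),
        bu_anion=totals["S_bu"] / COD_EQ_BU * KA_BU / (KA_BU + H),
        va_anion=totals["S_va"] / COD_EQ_VA * KA_VA / (KA_VA + H),
    )


def gas_outflow(P_head: float, k_p: float, P_atm: float = P_NORM) -> float:
    """Overpressure-driven biogas outflow (L/d at headspace conditions).

    q = k_p * (P_head - P_atm) * P_head / P_atm for P_head > P_atm, else 0.
    """
    if P_head <= 0.0:
        raise ValueError("headspace pressure must be positive")
    over = P_head - P_atm
    return k_p * over * P_head / P_atm if over > 0.0 else 0.0


def normalise_gas_flow(q: float, T: float, P: float) -> float:
    """Convert a volumetric flow at (T, P) to dry-norm conditions (273.15 K, 1 atm)."""
    return q * (T_NORM / T) * (P / P_NORM)
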