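"""State-vector layout of the two-guild anaerobic digestion model.

Liquid-phase organics are tracked in gCOD/L; inorganic carbon, inorganic
nitrogen and the strong-ion lumps in mol/L; the headspace as partial
pressures in bar.  Two auxiliary cumulative states carry the COD fed to and
exported from the reactor so that global mass-balance audits do not depend
on quadrature of saved output points.
"""

from __future__ import annotations

import numpy as np

# --- liquid phase: soluble ------------------------------------------------
S_SU, S_AA, S_FA, S_VA, S_BU, S_PRO, S_AC, S_H2, S_CH4 = range(9)
S_IC, S_IN, S_I = 9, 10, 11
# --- liquid phase: particulate --------------------------------------------
X_C, X_CH, X_PR, X_LI = 12, 13, 14, 15
X_SU, X_AA, X_FA, X_C4, X_PRO, X_AC1, X_AC2, X_H2, X_I = range(16, 25)
# --- strong ions ----------------------------------------------------------
S_CAT, S_AN = 25, 26
# --- headspace partial pressures (bar) ------------------------------------
P_H2, P_CH4, P_CO2 = 27, 28, 29
# --- cumulative audit states (gCOD) ---------------------------------------
CUM_COD_IN, CUM_COD_OUT = 30, 31

N_STATES = 32
N_LIQUID = 27  # states subject to hydraulic dilution

STATE_NAMES = [
    "S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac", "S_h2", "S_ch4",
    "S_IC", "S_IN", "S_I",
    "X_c", "X_ch", "X_pr", "X_li",
    "X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac1", "X_ac2", "X_h2", "X_I",
    "S_cat", "S_an",
    "p_h2", "p_ch4", "p_co2",
    "cum_cod_in", "cum_cod_out",
]

#: indices of the volatile fatty acid pools (gCOD/L)
VFA_INDICES = (S_VA, S_BU, S_PRO, S_AC)

#: indices of live biomass guilds (gCOD/L)
BIOMASS_INDICES = (X_SU, X_AA, X_FA, X_C4, X_PRO, X_AC1, X_AC2, X_H2)

#: liquid-phase states carrying COD (1 gCOD per unit); ions and S_IC do not
COD_MASK = np.zeros(N_STATES)
COD_MASK[[S_SU, S_AA, S_FA, S_VA, S_BU, S_PRO, S_AC, S_H2, S_CH4, S_I,
          X_C, X_CH, X_PR, X_LI,
          X_SU, X_AA, X_FA, X_C4, X_PRO, X_AC1, X_AC2, X_H2, X_I]] = 1.0


def empty_state() -> np.ndarray:
    """Return an all-zero state vector."""
    return np.zeros(N_STATES)
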