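"""Parameter sets: guild kinetics, ADM1 stoichiometry, physicochemistry.

The biochemical structure and default constants follow the IWA Anaerobic
Digestion Model No. 1 (Batstone et al., 2002) in the mesophilic benchmark
parameterisation of Rosen & Jeppsson (2006).  Two deviations define this
package: (i) the single acetoclastic guild is split into two competing
populations ("X_ac1" = Methanosarcina, "X_ac2" = Methanosaeta) with their
own kinetics and pH-inhibition windows, and (ii) the inorganic-carbon and
inorganic-nitrogen source terms of every process are generated from the
elemental contents of all other state variables so that each process row
closes C and N exactly (the benchmark tables leave small gaps, e.g. in
biomass decay).

Two named kinetic presets are provided for the five VFA/H2-converting
guilds: ``"this_study"`` (the fitted two-guild set) and ``"literature"``
(earlier published values with a single high-decay Methanosarcina and a
slow Methanosaeta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from . import state as st
from .kinetics import PopulationKinetics

GUILDS = ("X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac1", "X_ac2", "X_h2")

GUILD_STATE_INDEX = {
    "X_su": st.X_SU, "X_aa": st.X_AA, "X_fa": st.X_FA, "X_c4": st.X_C4,
    "X_pro": st.X_PRO, "X_ac1": st.X_AC1, "X_ac2": st.X_AC2, "X_h2": st.X_H2,
}

# fitted two-guild kinetics (acetic/propionic/butyric/hydrogen converters)
_THIS_STUDY = {
    "X_ac1": PopulationKinetics("X_ac1", Y=0.033, k_m=20.0, K=0.32, k_dec=0.02,
                                pH_ul=5.5, pH_ll=4.0),
    "X_ac2": PopulationKinetics("X_ac2", Y=0.033, k_m=14.5, K=0.09, k_dec=0.02,
                                pH_ul=7.0, pH_ll=6.3),
    "X_h2": PopulationKinetics("X_h2", Y=0.032, k_m=35.0, K=7e-6, k_dec=0.02,
                               pH_ul=6.0, pH_ll=5.0),
    "X_pro": PopulationKinetics("X_pro", Y=0.012, k_m=30.0, K=0.1, k_dec=0.02),
    "X_c4": PopulationKinetics("X_c4", Y=0.012, k_m=25.0, K=0.2, k_dec=0.02),
}

# earlier published values: fast-decaying Methanosarcina, slow Methanosaeta,
# remaining guilds at the ADM1 benchmark defaults
_LITERATURE = {
    "X_ac1": PopulationKinetics("X_ac1", Y=0.060, k_m=8.95, K=0.32, k_dec=0.1),
    "X_ac2": PopulationKinetics("X_ac2", Y=0.042, k_m=2.77, K=0.09, k_dec=0.0064),
    "X_h2": PopulationKinetics("X_h2", Y=0.060, k_m=35.0, K=7e-6, k_dec=0.02,
                               pH_ul=6.0, pH_ll=5.0),
    "X_pro": PopulationKinetics("X_pro", Y=0.040, k_m=13.0, K=0.1, k_dec=0.02),
    "X_c4": PopulationKinetics("X_c4", Y=0.060, k_m=20.0, K=0.2, k_dec=0.02),
}

# degraders upstream of acetogenesis, always at benchmark defaults
_ACIDOGENS = {
    "X_su": PopulationKinetics("X_su", Y=0.10, k_m=30.0, K=0.5, k_dec=0.02,
                               pH_ul=5.5, pH_ll=4.0),
    "X_aa": PopulationKinetics("X_aa", Y=0.08, k_m=50.0, K=0.3, k_dec=0.02,
                               pH_ul=5.5, pH_ll=4.0),
    "X_fa": PopulationKinetics("X_fa", Y=0.06, k_m=6.0, K=0.4, k_dec=0.02,
                               pH_ul=5.5, pH_ll=4.0),
}


@dataclass(frozen=True)
class Stoichiometry:
    """ADM1 product fractions and elemental contents.

    Carbon contents ``C_*`` are molC per gCOD (per mol for the inorganic
    pool), nitrogen contents ``N_*`` molN per gCOD.  Composite-disintegration
    fractions route decayed biomass back into carbohydrate/protein/lipid
    hydrolysis plus inerts.
    """

    # composite disintegration fractions (sum to 1)
    f_sI_xc: float = 0.1
    f_xI_xc: float = 0.2
    f_ch_xc: float = 0.2
    f_pr_xc: float = 0.2
    f_li_xc: float = 0.3
    # hydrolysis / disintegration first-order rates (1/d)
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0
    # lipid hydrolysis split
    f_fa_li: float = 0.95
    # acidogenesis product fractions (of the non-biomass COD)
    f_h2_su: float = 0.19
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_aa: float = 0.06
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40
    # acetogenesis product fractions
    f_h2_fa: float = 0.3
    f_ac_fa: float = 0.7
    f_h2_va: float = 0.15
    f_pro_va: float = 0.31  # propionate slice of valerate oxidation (ac = rest)
    f_h2_bu: float = 0.2
    f_h2_pro: float = 0.43
    # carbon contents (molC/gCOD)
    C_su: float = 0.0313
    C_aa: float = 0.03
    C_fa: float = 0.0217
    C_va: float = 0.024
    C_bu: float = 0.025
    C_pro: float = 0.0268
    C_ac: float = 0.0313
    C_ch4: float = 0.0156
    C_bac: float = 0.0313
    C_xc: float = 0.02786
    C_sI: float = 0.03
    C_xI: float = 0.03
    C_ch: float = 0.0313
    C_pr: float = 0.03
    C_li: float = 0.022
    # nitrogen contents (molN/gCOD)
    N_bac: float = 0.08 / 14.0
    N_aa: float = 0.007
    N_xc: float = 0.0376 / 14.0
    N_I: float = 0.06 / 14.0


@dataclass(frozen=True)
class Physicochemical:
    """Gas transfer, inhibition constants and auxiliary conversion factors."""

    k_L_a: float = 200.0          # liquid-gas transfer coefficient (1/d)
    k_p: float = 5.0e4            # gas outflow resistance (L/d per bar overpressure)
    P_atm: float = 1.01325        # ambient pressure (bar)
    K_S_IN: float = 1.0e-4        # inorganic-N limitation half constant (M)
    K_I_h2_fa: float = 5.0e-6     # H2 inhibition of LCFA oxidation (gCOD/L)
    K_I_h2_c4: float = 1.0e-5     # H2 inhibition of butyrate/valerate oxidation
    K_I_h2_pro: float = 3.5e-6    # H2 inhibition of propionate oxidation
    K_I_nh3: float = 1.8e-3       # free-ammonia inhibition of acetoclastics (M)
    cod_to_vs: float = 1.42       # gCOD per g volatile solids (biomass)
    ph_inhibition_form: str = "lower"


@dataclass(frozen=True)
class ParameterSet:
    """Full parameterisation: guild kinetics + stoichiometry + physicochemistry."""

    populations: Dict[str, PopulationKinetics]
    stoichiometry: Stoichiometry = field(default_factory=Stoichiometry)
    physicochemical: Physicochemical = field(default_factory=Physicochemical)

    def __post_init__(self) -> None:
        missing = set(GUILDS) - set(self.populations)
        if missing:
            raise ValueError(f"parameter set lacks guilds: {sorted(missing)}")

    def with_population(self, name: str, **overrides) -> "ParameterSet":
        """Return a copy with kinetic fields of one guild replaced."""
        pops = dict(self.populations)
        pops[name] = pops[name].replace(**overrides)
        return replace(self, populations=pops)

    def with_physicochemical(self, **overrides) -> "ParameterSet":
        return replace(self, physicochemical=replace(self.physicochemical, **overrides))


def preset(name: str = "this_study") -> ParameterSet:
    """Named kinetic preset: ``"this_study"`` or ``"literature"``."""
    if name == "this_study":
        pops = {**_ACIDOGENS, **_THIS_STUDY}
    elif name == "literature":
        pops = {**_ACIDOGENS, **_LITERATURE}
    else:
        raise KeyError(f"unknown parameter preset {name!r}")
    return ParameterSet(populations=dict(pops))


# ---------------------------------------------------------------------------
# Petersen matrix construction with exact elemental closure
# ---------------------------------------------------------------------------

PROCESS_NAMES = (
    "disintegration", "hydrolysis_ch", "hydrolysis_pr", "hydrolysis_li",
    "uptake_su", "uptake_aa", "uptake_fa", "uptake_va", "uptake_bu",
    "uptake_pro", "uptake_ac1", "uptake_ac2", "uptake_h2",
    "decay_su", "decay_aa", "decay_fa", "decay_c4", "decay_pro",
    "decay_ac1", "decay_ac2", "decay_h2",
)


def carbon_contents(s: Stoichiometry) -> np.ndarray:
    """molC per state unit for every state (S_IC itself carries 1 molC/mol)."""
    C = np.zeros(st.N_STATES)
    C[[st.S_SU, st.X_CH]] = s.C_su, s.C_ch
    C[st.S_AA] = s.C_aa
    C[st.S_FA] = s.C_fa
    C[st.S_VA] = s.C_va
    C[st.S_BU] = s.C_bu
    C[st.S_PRO] = s.C_pro
    C[st.S_AC] = s.C_ac
    C[st.S_CH4] = s.C_ch4
    C[st.S_IC] = 1.0
    C[st.S_I] = s.C_sI
    C[st.X_C] = s.C_xc
    C[st.X_PR] = s.C_pr
    C[st.X_LI] = s.C_li
    C[st.X_I] = s.C_xI
    for g in GUILDS:
        C[GUILD_STATE_INDEX[g]] = s.C_bac
    return C


def nitrogen_contents(s: Stoichiometry) -> np.ndarray:
    """molN per state unit for every state."""
    N = np.zeros(st.N_STATES)
    N[st.S_AA] = s.N_aa
    N[st.X_PR] = s.N_aa
    N[st.S_IN] = 1.0
    N[st.S_I] = s.N_I
    N[st.X_I] = s.N_I
    N[st.X_C] = s.N_xc
    for g in GUILDS:
        N[GUILD_STATE_INDEX[g]] = s.N_bac
    return N


def build_stoichiometric_matrix(params: ParameterSet) -> np.ndarray:
    """(N_STATES x n_processes) Petersen matrix of the biochemical system.

    The S_IC and S_IN rows are not tabulated but derived per process as the
    negative elemental-content-weighted sum of all other coefficients, so
    every process row closes carbon and nitrogen exactly by construction;
    COD closure holds because the tabulated product fractions sum to one.
    """
    s = params.stoichiometry
    pops = params.populations
    C = carbon_contents(s)
    N = nitrogen_contents(s)
    M = np.zeros((st.N_STATES, len(PROCESS_NAMES)))

    def set_proc(j: int, coeffs: Dict[int, float]) -> None:
        for idx, nu in coeffs.items():
            M[idx, j] = nu
        # close elemental balances through the inorganic pools
        M[st.S_IC, j] = -np.dot(C, M[:, j])
        M[st.S_IN, j] = -np.dot(N, M[:, j])

    set_proc(0, {st.X_C: -1.0, st.S_I: s.f_sI_xc, st.X_I: s.f_xI_xc,
                 st.X_CH: s.f_ch_xc, st.X_PR: s.f_pr_xc, st.X_LI: s.f_li_xc})
    set_proc(1, {st.X_CH: -1.0, st.S_SU: 1.0})
    set_proc(2, {st.X_PR: -1.0, st.S_AA: 1.0})
    set_proc(3, {st.X_LI: -1.0, st.S_FA: s.f_fa_li, st.S_SU: 1.0 - s.f_fa_li})

    Y = pops["X_su"].Y
    set_proc(4, {st.S_SU: -1.0, st.X_SU: Y,
                 st.S_H2: (1 - Y) * s.f_h2_su, st.S_BU: (1 - Y) * s.f_bu_su,
                 st.S_PRO: (1 - Y) * s.f_pro_su, st.S_AC: (1 - Y) * s.f_ac_su})
    Y = pops["X_aa"].Y
    set_proc(5, {st.S_AA: -1.0, st.X_AA: Y,
                 st.S_H2: (1 - Y) * s.f_h2_aa, st.S_VA: (1 - Y) * s.f_va_aa,
                 st.S_BU: (1 - Y) * s.f_bu_aa, st.S_PRO: (1 - Y) * s.f_pro_aa,
                 st.S_AC: (1 - Y) * s.f_ac_aa})
    Y = pops["X_fa"].Y
    set_proc(6, {st.S_FA: -1.0, st.X_FA: Y,
                 st.S_H2: (1 - Y) * s.f_h2_fa, st.S_AC: (1 - Y) * s.f_ac_fa})
    Y = pops["X_c4"].Y
    f_ac_va = 1.0 - s.f_h2_va - s.f_pro_va
    set_proc(7, {st.S_VA: -1.0, st.X_C4: Y,
                 st.S_H2: (1 - Y) * s.f_h2_va, st.S_PRO: (1 - Y) * s.f_pro_va,
                 st.S_AC: (1 - Y) * f_ac_va})
    set_proc(8, {st.S_BU: -1.0, st.X_C4: Y,
                 st.S_H2: (1 - Y) * s.f_h2_bu, st.S_AC: (1 - Y) * (1.0 - s.f_h2_bu)})
    Y = pops["X_pro"].Y
    set_proc(9, {st.S_PRO: -1.0, st.X_PRO: Y,
                 st.S_H2: (1 - Y) * s.f_h2_pro, st.S_AC: (1 - Y) * (1.0 - s.f_h2_pro)})
    Y = pops["X_ac1"].Y
    set_proc(10, {st.S_AC: -1.0, st.X_AC1: Y, st.S_CH4: 1 - Y})
    Y = pops["X_ac2"].Y
    set_proc(11, {st.S_AC: -1.0, st.X_AC2: Y, st.S_CH4: 1 - Y})
    Y = pops["X_h2"].Y
    set_proc(12, {st.S_H2: -1.0, st.X_H2: Y, st.S_CH4: 1 - Y})

    for j, g in enumerate(("X_su", "X_aa", "X_fa", "X_c4", "X_pro",
                           "X_ac1", "X_ac2", "X_h2")):
        set_proc(13 + j, {GUILD_STATE_INDEX[g]: -1.0, st.X_C: 1.0})

    return M
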