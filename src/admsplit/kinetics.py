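"""Guild-level Monod kinetics and pH inhibition.

Each microbial guild is described by a yield ``Y`` (gCOD biomass per gCOD
substrate), a maximum specific substrate utilisation rate ``k_m`` (gCOD
substrate per gCOD biomass per day), a half-saturation constant ``K``
(gCOD/L), a first-order decay rate ``k_dec`` (1/day) and, optionally, a pair
of pH-inhibition limits.  Inhibition sets in below the upper limit ``pH_ul``
and is essentially complete at the lower limit ``pH_ll``; guilds without
limits are not pH inhibited.  The asymmetric limits of the two acetoclastic
guilds (Methanosarcina tolerating pH well below 6, Methanosaeta already
inhibited below pH 7) are the niche mechanism that lets both coexist under
pulsed feeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class PopulationKinetics:
    """Kinetic/stoichiometric parameters of one microbial guild."""

    name: str
    Y: float          # gCOD_X / gCOD_S
    k_m: float        # gCOD_S / gCOD_X / d
    K: float          # gCOD_S / L
    k_dec: float      # 1/d
    pH_ul: Optional[float] = None  # inhibition starts below this pH
    pH_ll: Optional[float] = None  # inhibition complete at/below this pH

    def __post_init__(self) -> None:
        if not 0.0 < self.Y < 1.0:
            raise ValueError(f"{self.name}: yield must be in (0, 1), got {self.Y}")
        if self.k_m <= 0.0 or self.K <= 0.0:
            raise ValueError(f"{self.name}: k_m and K must be positive")
        if self.k_dec < 0.0:
            raise ValueError(f"{self.name}: k_dec must be non-negative")
        if self.pH_ul is not None and self.pH_ll is not None and self.pH_ll >= self.pH_ul:
            raise ValueError(f"{self.name}: pH_ll must lie below pH_ul")

    @property
    def mu_max(self) -> float:
        """Maximum gross specific growth rate Y*k_m (1/d)."""
        return self.Y * self.k_m

    def replace(self, **kwargs) -> "PopulationKinetics":
        from dataclasses import replace
        return replace(self, **kwargs)


def monod_uptake(S: float, X: float, kin: PopulationKinetics, I: float = 1.0) -> float:
    """Monod substrate utilisation rate k_m * S/(K+S) * X * I in gCOD/L/d.

    ``I`` is the combined (multiplicative) inhibition factor in [0, 1].
    """
    if S < 0.0 or X < 0.0:
        raise ValueError("substrate and biomass concentrations must be non-negative")
    if not 0.0 <= I <= 1.0:
        raise ValueError("inhibition factor must lie in [0, 1]")
    return kin.k_m * S / (kin.K + S) * X * I


def ph_inhibition(pH: float, kin: PopulationKinetics, form: str = "lower") -> float:
    """pH-inhibition factor in [0, 1] for a guild.

    ``form='lower'`` (default) is the lower-limit-only exponential used in the
    ADM1 benchmark implementation:

        I = exp(-3 * ((pH - pH_ul) / (pH_ul - pH_ll))**2)   for pH < pH_ul
        I = 1                                               otherwise

    ``form='hill'`` selects the switchable Michaelis-pseudo-two-protonation
    (Hill) alternative from the ADM1 report.  Guilds without configured limits
    return 1 (no pH inhibition).
    """
    if kin.pH_ul is None or kin.pH_ll is None:
        return 1.0
    if kin.pH_ul <= kin.pH_ll:
        raise ValueError(f"{kin.name}: pH_ul must exceed pH_ll")
    if form == "lower":
        if pH >= kin.pH_ul:
            return 1.0
        z = (pH - kin.pH_ul) / (kin.pH_ul - kin.pH_ll)
        return math.exp(-3.0 * z * z)
    if form == "hill":
        # centred two-sided form; K_pH at the midpoint, Hill slope from the gap
        K_ph = 10.0 ** (-0.5 * (kin.pH_ll + kin.pH_ul))
        n = 3.0 / (kin.pH_ul - kin.pH_ll)
        h = 10.0 ** (-pH)
        return K_ph ** n / (K_ph ** n + h ** n)
    raise ValueError(f"unknown pH inhibition form {form!r}")
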