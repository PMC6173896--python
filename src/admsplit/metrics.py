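"""Community analytics: Hill numbers, marker-gene corrections, unit maths.

Covers the small analytics used around the reactor experiments: Hill
diversity ``qD`` and evenness ``qE`` of relative-abundance profiles, the
conversion of 16S rRNA gene abundances to genome abundances via operon
copy numbers, the factor-2 correction for the two methanogen orders whose
*mrtA* isoenzyme gene doubles their *mcrA*-amplicon signal, the
interpretation of a [2-13C]-acetate labelling ratio, and stoichiometric
COD/mass/mol conversions of VFA mixtures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: methanogen orders carrying the mrtA isoenzyme gene (double amplicon signal)
MRTA_ORDERS = frozenset({"Methanobacteriales", "Methanococcales"})

#: gO2 per g acid (stoichiometric oxidation demand) and molar masses (g/mol)
VFA_COD_FACTORS = {"acetic": 64.0 / 60.05, "propionic": 112.0 / 74.08,
                   "butyric": 160.0 / 88.11, "valeric": 208.0 / 102.13}
VFA_MOLAR_MASS = {"acetic": 60.05, "propionic": 74.08,
                  "butyric": 88.11, "valeric": 102.13}


@dataclass(frozen=True)
class CommunityProfile:
    """Relative-abundance profile with optional per-taxon annotations."""

    labels: tuple
    abundances: np.ndarray
    copy_numbers: Optional[np.ndarray] = None   # 16S operons per genome
    orders: Optional[tuple] = None              # taxonomic order per label

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if len(self.labels) != ab.size:
            raise ValueError("labels and abundances differ in length")
        if np.any(ab < 0.0):
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1, got {ab.sum()!r}")
        object.__setattr__(self, "abundances", ab)
        if self.copy_numbers is not None:
            cn = np.asarray(self.copy_numbers, dtype=float)
            if cn.size != ab.size or np.any(cn < 1.0):
                raise ValueError("copy numbers must be >= 1, one per label")
            object.__setattr__(self, "copy_numbers", cn)

    @classmethod
    def from_counts(cls, labels: Sequence[str], counts: Sequence[float],
                    **kw) -> "CommunityProfile":
        counts = np.asarray(counts, dtype=float)
        return cls(labels=tuple(labels), abundances=counts / counts.sum(), **kw)

    def to_frame(self) -> pd.DataFrame:
        d = {"label": self.labels, "abundance": self.abundances}
        if self.copy_numbers is not None:
            d["copy_number"] = self.copy_numbers
        if self.orders is not None:
            d["order"] = self.orders
        return pd.DataFrame(d)


def hill_diversity(p: Sequence[float], q: float) -> float:
    """Hill number of order q: the effective number of equally common taxa.

    qD = (sum p_i^q)^(1/(1-q)) for q != 1; the q -> 1 limit is the
    exponential of the Shannon entropy (0*ln 0 taken as 0).  q = 0 counts
    taxa present (richness); q = 2 is the inverse Simpson concentration.
    """
    if q < 0.0:
        raise ValueError("diversity order q must be non-negative")
    p = np.asarray(p, dtype=float)
    p = p[p > 0.0]
    if p.size == 0:
        raise ValueError("profile has no nonzero abundances")
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def evenness(p: Sequence[float], q: float) -> float:
    """Hill evenness qE = qD / 0D, in (0, 1]."""
    return hill_diversity(p, q) / hill_diversity(p, 0.0)


def copy_number_correct(profile: CommunityProfile) -> CommunityProfile:
    """Convert gene-level to genome-level abundances: p_i' ~ p_i / c_i.

    Copy numbers come from the profile itself (one per taxon, typically a
    genus-level database value falling back to the next higher rank).
    """
    if profile.copy_numbers is None:
        raise ValueError("profile carries no copy numbers")
    w = profile.abundances / profile.copy_numbers
    return replace(profile, abundances=w / w.sum())


def mrta_correct(profile: CommunityProfile) -> CommunityProfile:
    """Halve the signal of the two mrtA-carrying orders, then renormalise.

    Members of Methanobacteriales and Methanococcales contribute two
    amplifiable methyl-coenzyme M reductase gene copies per genome (mcrA +
    mrtA), so their fragment abundance overstates genome abundance twofold.
    Taxa with unrecognised order annotations pass through unchanged.
    """
    if profile.orders is None:
        raise ValueError("profile carries no order annotations")
    w = profile.abundances.copy()
    known = MRTA_ORDERS | {None, ""}
    for i, order in enumerate(profile.orders):
        if order in MRTA_ORDERS:
            w[i] *= 0.5
        elif order not in known and not isinstance(order, str):
            logger.info("unknown order label %r passes through uncorrected", order)
    return replace(profile, abundances=w / w.sum())


def c13_pathway_ratio(labeled_co2: float, labeled_ch4: float) -> tuple[float, str]:
    """Ratio of 13C-labelled CO2 to 13C-labelled CH4 from [2-13C]-acetate.

    Acetoclastic methanogenesis routes the labelled methyl carbon into CH4
    (ratio << 1); syntrophic acetate oxidation routes it through CO2
    (ratio > 1).  Returns (ratio, dominant-pathway flag).
    """
    if labeled_co2 < 0.0 or labeled_ch4 < 0.0:
        raise ValueError("labelled gas amounts must be non-negative")
    if labeled_co2 == 0.0 and labeled_ch4 == 0.0:
        raise ValueError("at least one labelled gas amount must be positive")
    if labeled_ch4 == 0.0:
        return math.inf, "oxidative"
    ratio = labeled_co2 / labeled_ch4
    if ratio < 1.0:
        flag = "acetoclastic"
    elif ratio > 1.0:
        flag = "oxidative"
    else:
        flag = "boundary"
    return ratio, flag


def vfa_unit_convert(cod_fractions: Dict[str, float],
                     total_cod: float) -> pd.DataFrame:
    """Per-acid mass/molar concentrations of a COD-specified VFA mixture.

    Given COD fractions of named acids and a total COD (gCOD/L), returns a
    frame indexed by acid with columns ``cod`` (gCOD/L), ``mass`` (g/L),
    ``molar`` (M), ``cod_fraction``, ``mass_fraction``, ``mol_fraction``.
    """
    unknown = set(cod_fractions) - set(VFA_COD_FACTORS)
    if unknown:
        raise ValueError(f"unknown acid labels: {sorted(unknown)}")
    total_frac = sum(cod_fractions.values())
    if abs(total_frac - 1.0) > 1e-12:
        raise ValueError(f"COD fractions must sum to 1, got {total_frac!r}")
    rows = {}
    for acid, frac in cod_fractions.items():
        cod = frac * total_cod
        mass = cod / VFA_COD_FACTORS[acid]
        rows[acid] = {"cod": cod, "mass": mass,
                      "molar": mass / VFA_MOLAR_MASS[acid],
                      "cod_fraction": frac}
    df = pd.DataFrame(rows).T
    df["mass_fraction"] = df["mass"] / df["mass"].sum()
    df["mol_fraction"] = df["molar"] / df["molar"].sum()
    return df
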