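"""Synthetic observation tables and community profiles.

The generators emulate the measurement structure of the reactor study —
daily pre-feeding samples of VFA concentration, pH and volatile-solids
biomass, an occasional dense 24-h VFA/pH series across one feeding
interval, and methanogen composition snapshots — by sampling a simulated
trajectory and adding measurement noise: multiplicative lognormal noise on
concentrations and rates (default CV 10 %), additive Gaussian noise on pH
(default sd 0.05) and on composition fractions (default sd 0.02).  All
generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MRTA_ORDERS, CommunityProfile
from .model import Trajectory

#: observable -> trajectory column
QUANTITY_COLUMNS = {
    "VFA_total": "vfa_total", "VFA_ac": "S_ac", "VFA_pro": "S_pro",
    "VFA_bu": "S_bu", "pH": "pH", "VS_biomass": "biomass_vs",
    "f_sarcina": "f_sarcina", "CH4_rate": "q_ch4_norm",
}

_MULTIPLICATIVE = {"VFA_total", "VFA_ac", "VFA_pro", "VFA_bu",
                   "VS_biomass", "CH4_rate"}


@dataclass(frozen=True)
class ObservationSchedule:
    """When and what to sample.

    Daily samples are taken just before the feeding event (offset within
    the day configurable); one optional dense day adds a fine series across
    a full feeding interval.
    """

    quantities: Sequence[str] = ("VFA_total", "pH", "VS_biomass", "f_sarcina")
    daily_offset: float = 0.995          # fraction of a day (pre-feeding)
    dense_day: Optional[float] = None    # start of one 24-h fine series
    dense_days: Sequence[float] = ()     # additional 24-h fine series
    dense_step: float = 1.0 / 48.0       # 30 min
    dense_quantities: Sequence[str] = ("VFA_ac", "VFA_total", "pH")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise magnitudes."""

    cv: float = 0.10            # lognormal CV on concentrations/rates
    floor_sd: float = 0.01      # additive detection floor on concentrations
    ph_sd: float = 0.05         # additive sd on pH
    fraction_sd: float = 0.02   # additive sd on composition fractions


def _sample(traj: Trajectory, times: np.ndarray, column: str) -> np.ndarray:
    t = traj.times
    return np.interp(times, t, traj.df[column].to_numpy(dtype=float))


def generate_observations(traj: Trajectory,
                          schedule: Optional[ObservationSchedule] = None,
                          noise: Optional[NoiseSpec] = None,
                          seed: int = 0) -> pd.DataFrame:
    """Sample a trajectory into a tidy observation table.

    Returns rows of (time, quantity, value, noise_sd); values are clipped
    at zero except pH.  Concentration-like quantities combine relative
    (lognormal, CV) noise with an additive Gaussian detection floor, so
    trace-level readings do not pretend unlimited precision.  Reproducible
    given ``seed``.
    """
    schedule = schedule or ObservationSchedule()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    t0, t1 = traj.times[0], traj.times[-1]

    plan: list[tuple[float, str]] = []
    day0 = int(np.ceil(t0))
    for d in range(day0, int(np.floor(t1)) + 1):
        t = d - 1.0 + schedule.daily_offset
        if t0 <= t <= t1:
            plan.extend((t, q) for q in schedule.quantities)
    dense = list(schedule.dense_days)
    if schedule.dense_day is not None:
        dense.append(schedule.dense_day)
    for td in dense:
        if not (t0 <= td and td + 1.0 <= t1):
            raise ValueError("dense day lies outside the simulated horizon")
        for t in np.arange(td, td + 1.0 + 1e-9, schedule.dense_step):
            plan.extend((t, q) for q in schedule.dense_quantities)

    rows = []
    for t, q in plan:
        truth = float(_sample(traj, np.array([t]), QUANTITY_COLUMNS[q])[0])
        if q in _MULTIPLICATIVE:
            sigma = np.sqrt(np.log1p(noise.cv ** 2))
            value = truth * rng.lognormal(-0.5 * sigma ** 2, sigma) \
                if noise.cv > 0 else truth
            if noise.floor_sd > 0:
                value += rng.normal(0.0, noise.floor_sd)
            sd = float(np.hypot(noise.cv * truth, noise.floor_sd))
        elif q == "pH":
            value = truth + rng.normal(0.0, noise.ph_sd) if noise.ph_sd > 0 else truth
            sd = noise.ph_sd
        else:  # fractions
            value = truth + rng.normal(0.0, noise.fraction_sd) \
                if noise.fraction_sd > 0 else truth
            value = min(max(value, 0.0), 1.0)
            sd = noise.fraction_sd
        if q != "pH":
            value = max(value, 0.0)
        rows.append({"time": t, "quantity": q, "value": value, "noise_sd": sd})
    return pd.DataFrame(rows).sort_values(["time", "quantity"]).reset_index(drop=True)


_ORDER_POOL = ("Methanosarcinales", "Methanomicrobiales", "Methanobacteriales",
               "Methanococcales", "Methanocellales")


def generate_community_profiles(n_taxa: int, distribution: str = "dirichlet",
                                n_profiles: int = 1, seed: int = 0,
                                alpha: float = 1.0,
                                ratio: float = 0.5) -> list[CommunityProfile]:
    """Random relative-abundance profiles with copy numbers and orders.

    ``distribution``: ``"uniform"`` (perfectly even), ``"dirichlet"``
    (symmetric, concentration ``alpha``) or ``"geometric"`` (niche
    pre-emption series with the given ``ratio``).
    """
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_profiles):
        if distribution == "uniform":
            p = np.full(n_taxa, 1.0 / n_taxa)
        elif distribution == "dirichlet":
            p = rng.dirichlet(np.full(n_taxa, alpha))
        elif distribution == "geometric":
            p = ratio ** np.arange(n_taxa)
            p = p / p.sum()
        else:
            raise ValueError(f"unknown abundance distribution {distribution!r}")
        out.append(CommunityProfile(
            labels=tuple(f"taxon_{i}" for i in range(n_taxa)),
            abundances=p,
            copy_numbers=rng.integers(1, 8, size=n_taxa).astype(float),
            orders=tuple(rng.choice(_ORDER_POOL, size=n_taxa)),
        ))
    return out
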