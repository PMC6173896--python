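"""Reactor configuration, influent characterisation and feed schedules.

A feed schedule is a constant base flow plus a list of square pulse events
(each with its own flow and influent).  Continuous operation is a pure base
flow; discontinuous operation delivers a fraction of each period's ration
as a short pulse (20 min by default) with the remainder fed continuously.
Organic-overloading disturbances are extra pulse events of concentrated
substrate appended to a schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import state as st

MINUTES_20 = 20.0 / (24.0 * 60.0)  # 20 min in days

#: influent species label -> state index
SPECIES_INDEX = {
    "acetic": st.S_AC,
    "propionic": st.S_PRO,
    "butyric": st.S_BU,
    "valeric": st.S_VA,
    "sugar": st.S_SU,
    "amino_acids": st.S_AA,
    "lcfa": st.S_FA,
    "inert_soluble": st.S_I,
    "composite": st.X_C,
    "carbohydrate": st.X_CH,
    "protein": st.X_PR,
    "lipid": st.X_LI,
    "inert_particulate": st.X_I,
}


@dataclass(frozen=True)
class InfluentSpec:
    """Influent composition: total COD and its split over substrate species."""

    total_cod: float                      # gCOD/L
    cod_fractions: Dict[str, float]       # species label -> COD fraction
    inorganic_carbon: float = 0.0         # M
    inorganic_nitrogen: float = 0.0       # M

    def __post_init__(self) -> None:
        unknown = set(self.cod_fractions) - set(SPECIES_INDEX)
        if unknown:
            raise ValueError(f"unknown influent species: {sorted(unknown)}")
        if any(f < 0.0 for f in self.cod_fractions.values()):
            raise ValueError("COD fractions must be non-negative")
        total = sum(self.cod_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"COD fractions must sum to 1, got {total!r}")

    def scaled(self, factor: float) -> "InfluentSpec":
        return replace(self, total_cod=self.total_cod * factor)


@dataclass(frozen=True)
class ReactorConfig:
    """Geometry and operating conditions of one CSTR."""

    V_liq: float                 # L
    HRT: float                   # d
    influent: InfluentSpec
    T: float = 310.15            # K
    V_gas: Optional[float] = None   # L; defaults to V_liq / 10
    S_cat_in: float = 0.0783     # M
    S_an_in: float = 0.0198      # M

    def __post_init__(self) -> None:
        if self.V_liq <= 0.0 or self.HRT <= 0.0:
            raise ValueError("V_liq and HRT must be positive")
        if self.V_gas is not None and self.V_gas <= 0.0:
            raise ValueError("V_gas must be positive")

    @property
    def headspace(self) -> float:
        return self.V_gas if self.V_gas is not None else self.V_liq / 10.0

    @property
    def flow(self) -> float:
        """Long-run average influent flow V_liq/HRT (L/d)."""
        return self.V_liq / self.HRT


def influent_state_vector(spec: InfluentSpec, config: ReactorConfig) -> np.ndarray:
    """Influent concentrations mapped onto the model state layout."""
    y_in = st.empty_state()
    for label, frac in spec.cod_fractions.items():
        y_in[SPECIES_INDEX[label]] += frac * spec.total_cod
    y_in[st.S_IC] = spec.inorganic_carbon
    y_in[st.S_IN] = spec.inorganic_nitrogen
    y_in[st.S_CAT] = config.S_cat_in
    y_in[st.S_AN] = config.S_an_in
    return y_in


@dataclass(frozen=True)
class FeedEvent:
    """One square feeding pulse."""

    start: float        # d
    duration: float     # d
    flow: float         # L/d during the event
    influent: InfluentSpec

    def __post_init__(self) -> None:
        if self.duration <= 0.0:
            raise ValueError("event duration must be positive")
        if self.flow < 0.0:
            raise ValueError("event flow must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def cod_mass(self) -> float:
        """COD delivered by the event (g)."""
        return self.flow * self.duration * self.influent.total_cod


@dataclass(frozen=True)
class FeedSchedule:
    """Base continuous flow plus non-overlapping pulse events."""

    base_flow: float                       # L/d
    base_influent: InfluentSpec
    events: Tuple[FeedEvent, ...] = ()
    audit: Tuple[str, ...] = ()            # human-readable modification trail

    def __post_init__(self) -> None:
        ev = sorted(self.events, key=lambda e: e.start)
        for a, b in zip(ev, ev[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(f"overlapping feed events at t={b.start}")
        object.__setattr__(self, "events", tuple(ev))

    # -- queries -----------------------------------------------------------
    def edges(self, t0: float, t1: float) -> List[float]:
        """Sorted breakpoints of piecewise-constant feeding within [t0, t1]."""
        pts = {t0, t1}
        for e in self.events:
            for t in (e.start, e.end):
                if t0 < t < t1:
                    pts.add(t)
        return sorted(pts)

    def flow_and_influent(self, t: float) -> Tuple[float, Optional[FeedEvent]]:
        """Instantaneous total flow and the active event (if any) at time t."""
        for e in self.events:
            if e.start <= t < e.end:
                return self.base_flow + e.flow, e
        return self.base_flow, None

    def delivered_cod(self, t0: float, t1: float) -> float:
        """COD (g) delivered over [t0, t1]."""
        total = self.base_flow * (t1 - t0) * self.base_influent.total_cod
        for e in self.events:
            lo, hi = max(t0, e.start), min(t1, e.end)
            if hi > lo:
                total += e.flow * (hi - lo) * e.influent.total_cod
        return total

    def average_flow(self, t0: float, t1: float) -> float:
        vol = self.base_flow * (t1 - t0)
        for e in self.events:
            lo, hi = max(t0, e.start), min(t1, e.end)
            if hi > lo:
                vol += e.flow * (hi - lo)
        return vol / (t1 - t0)


def continuous_schedule(config: ReactorConfig) -> FeedSchedule:
    """Constant flow V_liq/HRT with the configured influent."""
    return FeedSchedule(base_flow=config.flow, base_influent=config.influent)


def discontinuous_schedule(config: ReactorConfig,
                           pulse_fraction: float = 1.0,
                           period: float = 1.0,
                           pulse_duration: float = MINUTES_20,
                           t_end: float = 400.0,
                           pulse_phase: float = 0.0) -> FeedSchedule:
    """Pulsed feeding: each period delivers ``pulse_fraction`` of the ration
    in one square pulse of ``pulse_duration`` days, the rest continuously.

    The long-run average flow equals V_liq/HRT regardless of the fraction.
    """
    if not 0.0 < pulse_fraction <= 1.0:
        raise ValueError("pulse_fraction must lie in (0, 1]")
    if pulse_duration >= period:
        raise ValueError("pulse_duration must be shorter than the period")
    ration_volume = config.flow * period               # L per period
    pulse_flow = pulse_fraction * ration_volume / pulse_duration
    base_flow = (1.0 - pulse_fraction) * config.flow
    n = int(math.ceil(t_end / period))
    events = tuple(
        FeedEvent(start=pulse_phase + k * period, duration=pulse_duration,
                  flow=pulse_flow, influent=config.influent)
        for k in range(n)
    )
    return FeedSchedule(base_flow=base_flow, base_influent=config.influent,
                        events=events)


def add_disturbance(schedule: FeedSchedule, day: float, extra_cod_g: float,
                    duration: float = MINUTES_20,
                    concentration_factor: float = 4.0) -> FeedSchedule:
    """Append an organic-overloading pulse of the base substrate mixture.

    The disturbance uses the same VFA mixture as the regular feed but at
    ``concentration_factor`` times the base influent concentration; its flow
    is then set so that exactly ``extra_cod_g`` grams of COD are delivered
    over ``duration``.  Overlap with an existing pulse merges the flows.
    """
    if extra_cod_g < 0.0:
        raise ValueError("extra COD must be non-negative")
    if extra_cod_g == 0.0:
        return schedule
    influent = schedule.base_influent.scaled(concentration_factor)
    flow = extra_cod_g / (influent.total_cod * duration)
    new = FeedEvent(start=day, duration=duration, flow=flow, influent=influent)
    events: List[FeedEvent] = []
    for e in schedule.events:
        if new is not None and e.start < new.end and new.start < e.end:
            # merge: summed flows, mass-weighted composition over the overlap
            lo = min(e.start, new.start)
            hi = max(e.end, new.end)
            mass = e.cod_mass + new.cod_mass
            vol = e.flow * e.duration + new.flow * new.duration
            merged_influent = replace(e.influent, total_cod=mass / vol)
            events.append(FeedEvent(start=lo, duration=hi - lo,
                                    flow=vol / (hi - lo),
                                    influent=merged_influent))
            new = None
        else:
            events.append(e)
    if new is not None:
        events.append(new)
    return replace(schedule, events=tuple(events),
                   audit=schedule.audit + (
                       f"disturbance day {day}: +{extra_cod_g:g} gCOD over {duration:g} d",))
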