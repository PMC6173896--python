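"""Shared fixtures: simulations are expensive, so trajectories used by
several test modules are computed once per session."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from admsplit.model import simulate
from admsplit.scenarios import preset


@pytest.fixture(scope="session")
def short_disco_traj():
    """Five days of the pulsed Experiment-1 reactor (fast, reused widely)."""
    sc = preset("exp1_disco", disturbed=False)
    return simulate(sc.config, sc.params, sc.schedule, 5.0, sc.y0)


@pytest.fixture(scope="session")
def exp1_pair():
    """Both Experiment-1 regimes through training and disturbance (day 80).

    This is the central simulation of the package; many assertions about
    competition, pH and resilience read from it.
    """
    out = {}
    for name in ("exp1_conti", "exp1_disco"):
        sc = preset(name, disturbed=True)
        out[name] = (sc, simulate(sc.config, sc.params, sc.schedule, 80.0,
                                  sc.y0))
    return out


@pytest.fixture(scope="session")
def recovery_setup():
    """Synthetic parameter-recovery experiment at the fitted kinetics.

    An acetate-only pulse-fed reactor observed like the real study (daily
    pre-feeding samples of VFA/pH/biomass/composition plus one dense 24-h
    VFA/pH series) with the default measurement noise, seeded.
    """
    import admsplit.state as st
    from admsplit.calibration import FitScenario
    from admsplit.feeding import InfluentSpec, ReactorConfig, discontinuous_schedule
    from admsplit.parameters import preset as param_preset
    from admsplit.synthetic import NoiseSpec, ObservationSchedule, generate_observations

    from admsplit.feeding import continuous_schedule

    params = param_preset("this_study")
    influent = InfluentSpec(total_cod=16.7, cod_fractions={"acetic": 1.0},
                            inorganic_carbon=0.005, inorganic_nitrogen=0.055)
    config = ReactorConfig(V_liq=6.0, HRT=5.5, influent=influent)
    y0 = np.zeros(st.N_STATES)
    y0[st.X_AC1], y0[st.X_AC2], y0[st.X_H2] = 0.45, 0.45, 0.10
    y0[st.S_AC], y0[st.S_IC], y0[st.S_IN] = 0.3, 0.09, 0.05
    y0[st.S_CAT], y0[st.S_AN] = 0.0783, 0.0198
    y0[st.P_CH4], y0[st.P_CO2] = 0.6, 0.35
    t_end = 12.0
    cases = {}
    for mode in ("disco", "conti"):
        if mode == "disco":
            schedule = discontinuous_schedule(config, pulse_fraction=1.0,
                                              t_end=20.0)
            obs_schedule = ObservationSchedule(dense_days=(6.0, 10.0))
        else:
            schedule = continuous_schedule(config)
            obs_schedule = ObservationSchedule()
        traj = simulate(config, params, schedule, t_end, y0, coarse_grid=0.02)
        scenario = FitScenario(name=mode, config=config, schedule=schedule,
                               y0=y0, t_end=t_end, training_end=t_end)
        cases[mode] = {"traj": traj, "scenario": scenario,
                       "obs_schedule": obs_schedule}
    return {"params": params, "cases": cases, "noise": NoiseSpec()}


@pytest.fixture(scope="session")
def recovery_fit(recovery_setup):
    """Recovered acetoclastic kinetics from the seeded noisy observations."""
    from admsplit.calibration import fit_to_observations
    from admsplit.synthetic import generate_observations

    obs, scenarios = [], []
    for i, case in enumerate(recovery_setup["cases"].values()):
        obs.append(generate_observations(case["traj"], case["obs_schedule"],
                                         recovery_setup["noise"],
                                         seed=2021 + i))
        scenarios.append(case["scenario"])
    truth = recovery_setup["params"]
    start = (truth.with_population("X_ac1", k_m=26.0, K=0.22)
             .with_population("X_ac2", k_m=11.0, K=0.13))
    names = ["X_ac1.k_m", "X_ac1.K", "X_ac2.k_m", "X_ac2.K"]
    bounds = {"X_ac1.k_m": (5.0, 80.0), "X_ac1.K": (0.08, 1.3),
              "X_ac2.k_m": (3.6, 58.0), "X_ac2.K": (0.02, 0.36)}
    return fit_to_observations(start, names, bounds, obs, scenarios,
                               seed=2021, coarse_grid=0.02)


@pytest.fixture(scope="session")
def literature_conti_traj():
    """Continuous Experiment-1 reactor under the literature kinetics."""
    sc = preset("exp1_conti", disturbed=False, parameter_preset="literature")
    return simulate(sc.config, sc.params, sc.schedule, 40.0, sc.y0)


@pytest.fixture(scope="session")
def maize_switch():
    """Maize-silage digester: continuous to steady state, then switch to
    every-second-day feeding with Methanosarcina re-seeded at 0.2 gCOD/L."""
    import admsplit.state as st
    from admsplit.model import find_steady_state

    conti = preset("maize_conti")
    y_ss, _ = find_steady_state(conti.config, conti.params, conti.schedule,
                                conti.y0, t_max=250.0, chunk=50.0, tol=1e-4)
    disco = preset("maize_disco", t_end=400.0)
    y0 = y_ss.copy()
    y0[st.X_AC1] = 0.2
    traj = simulate(disco.config, disco.params, disco.schedule, 365.0, y0)
    return {"steady_state": y_ss, "trajectory": traj}
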