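"""Fit machinery: summaries, objective properties, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from admsplit.calibration import (FitScenario, FitSummary, FitTargets,
                                  objective, summarize, washout_hrt)
from admsplit.parameters import preset


class TestSummarize:
    def test_constant_trajectory_summary_equals_the_constants(self,
                                                              short_disco_traj):
        # build a synthetic constant trajectory by freezing one state row
        traj = short_disco_traj
        df = traj.df.iloc[[10] * 40].copy()
        df["time"] = np.linspace(0.0, 39.0, 40)
        frozen = type(traj)(df=df.reset_index(drop=True), config=traj.config,
                            params=traj.params, schedule=traj.schedule)
        s = summarize(frozen, training_end_day=39.0)
        row = traj.df.iloc[10]
        assert s.biomass_vs_end == pytest.approx(row["biomass_vs"])
        assert s.vfa_end == pytest.approx(row["vfa_total"])
        assert s.ph_max_training == pytest.approx(row["pH"])
        assert s.dic_range[0] == pytest.approx(s.dic_range[1])

    def test_horizon_too_short_raises(self, short_disco_traj):
        with pytest.raises(ValueError):
            summarize(short_disco_traj, training_end_day=1000.0)


class TestObjective:
    def _targets_from(self, summary: FitSummary, weights=None):
        vals = summary.as_dict()
        return FitTargets(values=vals, weights=weights or {})

    def test_zero_iff_targets_equal_summaries(self, short_disco_traj):
        import admsplit.state as st
        sc = FitScenario(name="d", config=short_disco_traj.config,
                         schedule=short_disco_traj.schedule,
                         y0=short_disco_traj.df.iloc[0][
                             st.STATE_NAMES].to_numpy(dtype=float),
                         t_end=5.0, training_end=5.0)
        params = short_disco_traj.params
        summary = summarize(short_disco_traj, 5.0)
        targets = {"d": self._targets_from(summary)}
        val = objective(params, targets, [sc])
        assert val == pytest.approx(0.0, abs=1e-6)
        # doubling one weight doubles that term
        off_targets = {"d": FitTargets(
            values={"vfa_end": summary.vfa_end * 1.5},
            weights={"vfa_end": 1.0})}
        base = objective(params, off_targets, [sc])
        doubled = {"d": FitTargets(values={"vfa_end": summary.vfa_end * 1.5},
                                   weights={"vfa_end": 2.0})}
        assert objective(params, doubled, [sc]) == pytest.approx(2 * base,
                                                                 rel=1e-9)

    def test_fitted_kinetics_beat_literature_kinetics_on_the_study_targets(
            self, exp1_pair):
        """The two-guild parameter set scores strictly better than the
        earlier literature values against the study's own end-of-training
        targets (coexistence under pulsing, Methanosaeta dominance under
        continuous feeding)."""
        scenarios = []
        targets = {}
        paper_targets = {
            "exp1_conti": {"f_sarcina_end": 0.002, "ph_max_training": 7.29},
            "exp1_disco": {"f_sarcina_end": 0.56, "ph_max_training": 7.56},
        }
        for name, (sc, traj) in exp1_pair.items():
            scenarios.append(FitScenario(
                name=name, config=sc.config, schedule=sc.schedule, y0=sc.y0,
                t_end=64.0, training_end=64.0))
            targets[name] = FitTargets(values=paper_targets[name])
        fitted = objective(preset("this_study"), targets, scenarios)
        literature = objective(preset("literature"), targets, scenarios)
        assert fitted < literature


class TestParameterRecovery:
    def test_acetoclastic_km_and_K_recovered_within_15_percent(self,
                                                               recovery_fit):
        """Seeded synthetic observations generated at the fitted kinetics
        allow both guilds' uptake parameters to be re-estimated within 15 %
        despite 10 % concentration noise, starting from a biased guess."""
        truth = {"X_ac1.k_m": 20.0, "X_ac1.K": 0.32,
                 "X_ac2.k_m": 14.5, "X_ac2.K": 0.09}
        diag = recovery_fit.diagnostics.set_index("parameter")
        for name, true_val in truth.items():
            fitted = diag.loc[name, "fitted"]
            assert abs(fitted - true_val) / true_val < 0.15, (name, fitted)

    def test_fit_moved_away_from_the_biased_start(self, recovery_fit):
        diag = recovery_fit.diagnostics.set_index("parameter")
        assert abs(diag.loc["X_ac1.k_m", "fitted"]
                   - diag.loc["X_ac1.k_m", "initial"]) > 1.0
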