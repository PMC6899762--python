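"""Correlated outcome generation, observation models, OC aggregation."""

import numpy as np
import pytest
from scipy.stats import kstest

from wedesign import (
    ObservationModel,
    Scenario,
    ScenarioOracle,
    apply_observation_model,
    builtin_scenarios,
    draw_patient,
    simulate_oc,
    single_agent_design,
)
from wedesign.simulate import replicate_rng


class TestBuiltinScenarios:
    def test_catalogue_shape(self, scenarios):
        assert set(scenarios) == set(range(1, 10))
        for i in range(1, 7):
            assert scenarios[i].layout == "single" and scenarios[i].m == 4
        for i in range(7, 10):
            assert scenarios[i].layout == "combination" and scenarios[i].m == 8

    def test_scenario_1_values(self, scenarios):
        sc = scenarios[1]
        assert sc.p_t == (0.01, 0.15, 0.45, 0.65)
        assert sc.mu == (0.5, -0.5, -1.5, -3.0)
        assert sc.obr == 1  # dA2

    def test_scenario_9_first_agent_row(self, scenarios):
        sc = scenarios[9]
        assert sc.p_t[:4] == (0.01, 0.15, 0.40, 0.50)
        assert sc.mu[:4] == (0.0, -2.0, -2.0, -2.0)
        assert sc.obr == 1  # (dA2, dB1)
        assert sc.labels[1] == "(dA2,dB1)"

    def test_no_obr_scenarios(self, scenarios):
        assert scenarios[5].obr is None
        assert scenarios[6].obr is None

    def test_defaults(self, scenarios):
        for sc in scenarios.values():
            assert sc.sigma == 1.0 and sc.r == 0.2


class TestTateGenerator:
    def test_margins_at_weak_correlation(self):
        rng = np.random.default_rng(101)
        sc = Scenario("m", (0.15,), (-0.5,), obr=None, r=0.2)
        tox, eff = ScenarioOracle(sc).draw(0, 100_000, rng)
        n = tox.size
        se_t = np.sqrt(0.15 * 0.85 / n)
        assert abs(tox.mean() - 0.15) < 3 * se_t
        assert abs(eff.mean() + 0.5) < 3 / np.sqrt(n)
        assert abs(eff.std() - 1.0) < 0.02

    @pytest.mark.parametrize("r", [-0.8, 0.0, 0.8])
    def test_margins_invariant_to_correlation(self, r):
        rng = np.random.default_rng(7)
        sc = Scenario("m", (0.5,), (1.0,), obr=None, r=r)
        tox, eff = ScenarioOracle(sc).draw(0, 100_000, rng)
        assert abs(tox.mean() - 0.5) < 3 * np.sqrt(0.25 / tox.size)
        assert abs(eff.mean() - 1.0) < 3 / np.sqrt(eff.size)
        # efficacy margin stays standard normal around its mean
        assert kstest(eff - eff.mean(), "norm").pvalue > 1e-3

    def test_coupling_orientation(self):
        """Positive r pairs toxicity with lower (better-coded) efficacy."""
        rng = np.random.default_rng(11)
        sc = Scenario("m", (0.5,), (0.0,), obr=None, r=0.8)
        tox, eff = ScenarioOracle(sc).draw(0, 100_000, rng)
        rho = np.corrcoef(tox, eff)[0, 1]
        assert rho < -0.3
        rng = np.random.default_rng(11)
        sc = Scenario("m", (0.5,), (0.0,), obr=None, r=-0.8)
        tox2, eff2 = ScenarioOracle(sc).draw(0, 100_000, rng)
        assert np.corrcoef(tox2, eff2)[0, 1] > 0.3

    def test_zero_toxicity_boundary(self):
        tox, _ = ScenarioOracle(
            Scenario("m", (0.0,), (0.0,), obr=None, r=0.2)
        ).draw(0, 10_000, np.random.default_rng(0))
        assert tox.sum() == 0

    def test_draw_patient_scalar_interface(self, rng):
        tox, eff = draw_patient(0.3, -1.0, 1.0, 0.2, rng)
        assert tox in (0, 1) and np.isfinite(eff)

    def test_invalid_correlation(self, rng):
        with pytest.raises(ValueError):
            draw_patient(0.3, -1.0, 1.0, 1.0, rng)


class TestObservationModel:
    timeline = [
        # (cohort, regimen, toxicity, efficacy)
        (1, 1, 0, -0.5), (1, 1, 1, 0.3), (1, 1, 0, -1.2),
        (2, 2, 0, -0.8), (2, 2, 0, -0.1), (2, 2, 1, 0.9),
    ]

    def test_identity_view(self):
        df = apply_observation_model(self.timeline, ObservationModel(), 2)
        assert len(df) == 6
        assert df["efficacy"].notna().sum() == 6

    def test_missing_on_toxicity(self):
        model = ObservationModel(missing_on_toxicity=True)
        df = apply_observation_model(self.timeline[:3], model, 1)
        assert len(df) == 3  # three toxicity observations
        assert df["efficacy"].notna().sum() == 2  # toxic patient's efficacy removed

    def test_delayed_lag(self):
        model = ObservationModel(delayed=True)
        df = apply_observation_model(self.timeline, model, 2)
        vis = df[df["efficacy"].notna()]
        assert set(vis["cohort"]) == {1}  # cohort 2 efficacy not yet visible
        assert len(df) == 6  # toxicity of both cohorts visible

    def test_engine_uses_fewer_efficacy_observations_when_missing(self, scenarios):
        from wedesign import run_trial

        cfg = single_agent_design()
        oracle = ScenarioOracle(scenarios[2])
        model = ObservationModel(missing_on_toxicity=True)
        res = run_trial(oracle, cfg, replicate_rng(3, 0), observation_model=model)
        assert res.tox_count > 0
        # every generated efficacy value is still counted in the burden metric
        assert res.eff_values.size == res.treated


class TestSimulateOC:
    def test_single_replicate_equals_trial(self, scenarios, single_config):
        rep, results = simulate_oc(
            scenarios[1], single_config, reps=1, seed=42, collect_results=True
        )
        res = results[0]
        assert rep.reps == 1
        if res.recommendation is None:
            assert rep.termination_pct == 100.0
        else:
            assert rep.selection_pct[res.recommendation] == 100.0
        assert rep.avg_toxicity_pct == pytest.approx(100 * res.tox_count / res.treated)
        assert rep.avg_efficacy == pytest.approx(res.eff_values.mean())

    def test_selection_and_termination_sum_to_100(self, scenarios, single_config):
        rep = simulate_oc(scenarios[1], single_config, reps=200, seed=5)
        assert rep.selection_pct.sum() + rep.termination_pct == pytest.approx(100.0)

    def test_average_toxicity_below_scenario_maximum(self, scenarios, single_config):
        rep = simulate_oc(scenarios[2], single_config, reps=200, seed=5)
        assert rep.avg_toxicity_pct <= 100 * max(scenarios[2].p_t)

    def test_bitwise_reproducibility(self, scenarios, single_config):
        a = simulate_oc(scenarios[3], single_config, reps=50, seed=9)
        b = simulate_oc(scenarios[3], single_config, reps=50, seed=9)
        assert a.to_dict() == b.to_dict()
        c = simulate_oc(scenarios[3], single_config, reps=50, seed=10)
        assert a.to_dict() != c.to_dict()

    def test_layout_mismatch_rejected(self, scenarios, combo_config, single_config):
        with pytest.raises(ValueError):
            simulate_oc(scenarios[7], single_config, reps=1, seed=0)
        with pytest.raises(ValueError):
            simulate_oc(scenarios[1], combo_config, reps=1, seed=0)

    def test_report_serialisation(self, scenarios, single_config):
        rep = simulate_oc(scenarios[1], single_config, reps=20, seed=1)
        df = rep.to_dataframe()
        assert list(df["regimen"])[:4] == list(scenarios[1].labels)
        assert "termination" in set(df["regimen"])
        assert "selection_pct" in rep.to_json()
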