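"""Trial engine: schedules, admissibility, allocation, full trial runs."""

import numpy as np
import pytest

from wedesign import (
    DesignConfig,
    EfficacyPosterior,
    RegimenOrdering,
    RegimenState,
    Scenario,
    ScenarioOracle,
    ToxicityPosterior,
    admissible_regimens,
    allocation_probabilities,
    allocate_next_cohort,
    eta_schedule,
    plug_in_delta,
    run_trial,
    single_agent_design,
    trade_off_marginal,
    transform_value,
)


def states_with(config, updates):
    """Prior states with (regimen -> (tox_count, n, efficacy list)) applied."""
    states = config.prior_states()
    out = []
    for j, s in enumerate(states):
        if j in updates:
            t, n, eff = updates[j]
            s = RegimenState(tox=s.tox.update(t, n), eff=s.eff.update(eff))
        out.append(s)
    return out


class TestSchedules:
    def test_before_any_data(self):
        assert eta_schedule(0, 0.95, 0.02, 0.6) == pytest.approx(0.95)
        assert eta_schedule(0, 0.80, 0.02, 0.3) == pytest.approx(0.80)

    def test_floor_reached(self):
        assert eta_schedule(20, 0.95, 0.02, 0.6) == pytest.approx(0.6)

    def test_linear_segment(self):
        assert eta_schedule(5, 0.95, 0.02, 0.6) == pytest.approx(0.85)

    def test_monotone_nonincreasing(self):
        ns = np.arange(0, 40)
        vals = eta_schedule(ns, 0.95, 0.02, 0.6)
        assert np.all(np.diff(vals) <= 0)


class TestOrdering:
    def test_chain(self):
        o = RegimenOrdering.chain(4)
        assert o.above[0, 3] and o.above[2, 3] and not o.above[3, 2]
        assert o.predecessors == ((), (0,), (1,), (2,))

    def test_grid_product_order(self):
        o = RegimenOrdering.grid(4, 2)  # index = b*4 + a
        # (dA1,dB1)=0 below everything; (dA2,dB1)=1 vs (dA1,dB2)=4 incomparable
        assert o.above[0].sum() == 7
        assert not o.above[1, 4] and not o.above[4, 1]
        assert o.above[1, 5]  # (dA2,dB1) < (dA2,dB2)
        assert set(o.predecessors[5]) == {4, 1}

    def test_start_must_be_minimal(self):
        with pytest.raises(ValueError):
            single_agent_design(start_regimen=2)


class TestConfigValidation:
    def test_prior_mass_bounds(self):
        with pytest.raises(ValueError):
            single_agent_design(prior_tox=(0.1, 0.2, 0.3, 1.5))

    def test_allocation_enum(self):
        with pytest.raises(ValueError):
            single_agent_design(allocation="bogus")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            DesignConfig(
                m=4, n_max=36, nu=(0.1, 0.2), mu0=(-1.0,) * 4,
                ordering=RegimenOrdering.chain(4),
            )


class TestAdmissibility:
    def test_untried_regimens_admissible_under_priors(self, single_config):
        mask = admissible_regimens(single_config.prior_states(), single_config)
        assert mask.all()

    def test_all_toxic_flags_unsafe_and_propagates(self, single_config):
        # 6/6 toxicities at the lowest dose: tail ~ 1 >= eta1(6) = 0.83
        states = states_with(single_config, {0: (6, 6, [])})
        mask = admissible_regimens(states, single_config)
        assert not mask.any()  # unsafety propagates up the chain

    def test_unsafe_midchain_spares_lower_doses(self, single_config):
        states = states_with(single_config, {2: (6, 6, [])})
        mask = admissible_regimens(states, single_config)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_flags_honoured_from_state(self, single_config):
        states = single_config.prior_states()
        states[1] = RegimenState(tox=states[1].tox, eff=states[1].eff, futile=True)
        mask = admissible_regimens(states, single_config)
        np.testing.assert_array_equal(mask, [True, False, True, True])

    def test_constraints_monotone_in_controlling_probability(self, single_config):
        from dataclasses import replace

        states = states_with(single_config, {1: (3, 6, [])})
        strict = replace(single_config, eta1_0=0.5, eta1_bar=0.3)
        lax_mask = admissible_regimens(states, single_config)
        strict_mask = admissible_regimens(states, strict)
        # anything inadmissible under the lax threshold stays inadmissible
        assert np.all(strict_mask <= lax_mask)


class TestPlugInDelta:
    def test_composition_of_verified_operations(self, single_config, target):
        state = single_config.prior_states()[0]
        pe = transform_value(-1.0, single_config.transform)
        assert pe == pytest.approx(0.0437, abs=1e-4)
        expected = trade_off_marginal(0.10, pe, target)
        assert plug_in_delta(state, single_config) == pytest.approx(expected, rel=1e-12)

    def test_zero_at_exact_target(self, single_config, target):
        # a regimen whose posterior mean sits exactly on the target profile
        xi_target = (np.log(0.99 / 0.01) - single_config.transform.alpha) / (
            single_config.transform.beta
        )
        tox = ToxicityPosterior(nu=0.01, beta_strength=1.0)
        eff = EfficacyPosterior(mu0=xi_target, lam=1.0)
        assert plug_in_delta(RegimenState(tox, eff), single_config) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_monotone_preference_for_target_efficacy(self, single_config):
        # at equal toxicity, efficacy near the best feasible value wins
        tox = ToxicityPosterior(nu=0.01, beta_strength=1.0)
        good = RegimenState(tox, EfficacyPosterior(mu0=-4.4))
        bad = RegimenState(tox, EfficacyPosterior(mu0=0.0))
        assert plug_in_delta(good, single_config) < plug_in_delta(bad, single_config)


class TestAllocation:
    def test_proportionality(self, single_config, monkeypatch):
        from wedesign.engine import _top_two

        deltas = np.array([1.0, 3.0, 50.0, 60.0])
        top, probs = _top_two(deltas, np.ones(4, dtype=bool), np.zeros(4))
        np.testing.assert_array_equal(top, [0, 1])
        np.testing.assert_allclose(probs, [0.75, 0.25])

    def test_zero_scores_split_evenly(self):
        from wedesign.engine import _top_two

        top, probs = _top_two(np.zeros(2), np.ones(2, dtype=bool), np.zeros(2))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_single_candidate_probability_one(self, single_config):
        states = single_config.prior_states()
        cand, probs = allocation_probabilities(states, single_config)
        # only the start regimen is reachable before any data (no skipping)
        np.testing.assert_array_equal(cand, [0])
        np.testing.assert_allclose(probs, [1.0])

    def test_empty_candidate_set_signals_termination(self, single_config, rng):
        states = states_with(single_config, {0: (6, 6, [])})
        assert allocate_next_cohort(states, single_config, rng) is None

    def test_top_two_after_first_cohort(self, single_config, rng):
        states = states_with(single_config, {0: (0, 3, [0.4, 0.6, 0.2])})
        cand, probs = allocation_probabilities(states, single_config)
        assert set(cand) == {0, 1}
        assert probs.sum() == pytest.approx(1.0)
        choice = allocate_next_cohort(states, single_config, rng)
        assert choice in (0, 1)


def _zero_tox_scenario():
    # efficacy of the second regimen sits at the target probability 0.99;
    # all other regimens are clearly inferior, so the design should settle
    # there as the patient budget grows
    from wedesign import TransformSpec, inverse_transform

    spec = TransformSpec.from_anchors(0.0, -4.5)
    xi = inverse_transform(0.99, spec)
    return Scenario(
        "consistency", (0.001, 0.001, 0.001, 0.001), (0.0, xi, -1.0, -0.5),
        obr=1, r=0.0,
    )


class TestRunTrial:
    def test_zero_patients_terminates(self, single_config, rng):
        from dataclasses import replace

        cfg = replace(single_config, n_max=0)
        oracle = ScenarioOracle(_zero_tox_scenario())
        res = run_trial(oracle, cfg, rng)
        assert res.terminated and res.recommendation is None
        assert res.treated == 0

    def test_budget_respected_and_first_cohort_at_start(self, single_config, rng):
        oracle = ScenarioOracle(_zero_tox_scenario())
        res = run_trial(oracle, single_config, rng, collect_log=True)
        assert res.n_assigned.sum() == res.treated <= single_config.n_max
        assert res.n_assigned[single_config.start_regimen] >= 3

    def test_terminated_iff_no_recommendation(self, single_config, scenarios):
        from wedesign.simulate import replicate_rng

        oracle = ScenarioOracle(scenarios[5])
        for k in range(10):
            res = run_trial(oracle, single_config, replicate_rng(5, k))
            assert res.terminated == (res.recommendation is None)

    def test_consistency_at_large_n(self, single_config):
        from dataclasses import replace

        cfg = replace(single_config, n_max=600)
        oracle = ScenarioOracle(_zero_tox_scenario())
        res = run_trial(oracle, cfg, np.random.default_rng(3))
        assert res.recommendation == 1
        assert res.n_assigned[1] > 0.8 * cfg.n_max

    def test_recommendation_minimises_delta_over_final_admissible(self, scenarios):
        from wedesign.simulate import replicate_rng

        cfg = single_agent_design()
        oracle = ScenarioOracle(scenarios[1])
        checked = 0
        for k in range(40):
            res = run_trial(oracle, cfg, replicate_rng(11, k))
            if res.recommendation is not None:
                ok = res.final_admissible
                assert ok[res.recommendation]
                assert res.final_deltas[res.recommendation] == pytest.approx(
                    res.final_deltas[ok].min()
                )
                checked += 1
        assert checked > 10

    def test_determinism_same_seed(self, single_config, scenarios):
        from wedesign.simulate import replicate_rng

        oracle = ScenarioOracle(scenarios[2])
        a = run_trial(oracle, single_config, replicate_rng(7, 0), collect_log=True)
        b = run_trial(oracle, single_config, replicate_rng(7, 0), collect_log=True)
        np.testing.assert_array_equal(a.n_assigned, b.n_assigned)
        assert a.recommendation == b.recommendation
        assert a.decision_log == b.decision_log


class TestCoherenceInvariants:
    def _replay(self, res, cfg):
        """Reconstruct cohort assignments and check the coherence rules."""
        n = np.zeros(cfg.m)
        assignment = [cfg.start_regimen] * cfg.cohort_size
        prev_unsafe = np.zeros(cfg.m, dtype=bool)
        prev_futile = np.zeros(cfg.m, dtype=bool)
        for entry in res.decision_log:
            for j in assignment:
                n[j] += 1
            if entry.get("event") == "terminated":
                break
            # absorbing flags
            unsafe = np.array(entry["unsafe"])
            futile = np.array(entry["futile"])
            assert np.all(unsafe >= prev_unsafe) and np.all(futile >= prev_futile)
            prev_unsafe, prev_futile = unsafe, futile
            nxt = entry["next_assignment"]
            for j in set(nxt):
                # no escalation above a regimen with excessive cohort toxicity
                for d, frac in entry["tox_fractions"].items():
                    if frac >= cfg.phi:
                        assert not cfg.ordering.above[int(d), j]
                # no skipping: untried regimens need all predecessors tried
                if n[j] == 0:
                    assert all(n[p] > 0 for p in cfg.ordering.predecessors[j])
                # flagged regimens are never treated
                assert not unsafe[j] and not futile[j]
            assignment = nxt
        for j in assignment:
            n[j] += 1

    def test_replayed_logs_satisfy_coherence(self, scenarios):
        from wedesign.simulate import replicate_rng

        cfg = single_agent_design()
        oracle = ScenarioOracle(scenarios[1])
        for k in range(40):
            res = run_trial(oracle, cfg, replicate_rng(13, k), collect_log=True)
            self._replay(res, cfg)

    def test_combination_no_skipping(self, scenarios, combo_config):
        from wedesign.simulate import replicate_rng

        oracle = ScenarioOracle(scenarios[7])
        for k in range(15):
            res = run_trial(oracle, combo_config, replicate_rng(17, k), collect_log=True)
            self._replay(res, combo_config)
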