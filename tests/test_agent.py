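import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.agent import (AgentState, ParameterSet, model_based_values,
                           session_neg_log_likelihood, simulate_session,
                           stage1_choice_probs, stage2_choice_probs, td_update)
from twostep.errors import ConfigError
from twostep.task import TaskConfig, build_reward_schedule

from conftest import random_session
from oracle import oracle_session_nll

UNIFORM = ParameterSet(alpha1=0.5, alpha2=0.5, lam=0.5, beta2=0.0,
                       beta_hb=0.0, beta_gd=0.0, p=0.0)


def params_strategy():
    return st.builds(
        ParameterSet,
        alpha1=st.floats(0.01, 0.99), alpha2=st.floats(0.01, 0.99),
        lam=st.floats(0.01, 0.99), beta2=st.floats(0.0, 15.0),
        beta_hb=st.floats(0.0, 15.0), beta_gd=st.floats(0.0, 15.0),
        p=st.floats(-3.0, 3.0),
    )


class TestParameterSet:
    def test_has_exactly_seven_free_parameters(self, mid_params):
        assert len(mid_params.as_array()) == 7

    @pytest.mark.parametrize(
        "kwargs", [{"alpha1": 0.0}, {"alpha2": 1.0}, {"lam": -0.1},
                   {"beta2": -1.0}, {"beta_gd": -0.01}]
    )
    def test_out_of_bound_values_rejected(self, kwargs):
        base = dict(alpha1=0.5, alpha2=0.5, lam=0.5, beta2=1.0,
                    beta_hb=1.0, beta_gd=1.0, p=0.0)
        with pytest.raises(ConfigError):
            ParameterSet(**{**base, **kwargs})

    def test_relative_goal_directed_weight(self):
        ps = ParameterSet(0.5, 0.5, 0.5, 1.0, beta_hb=1.0, beta_gd=3.0, p=0.0)
        assert ps.omega == pytest.approx(0.75)


class TestModelBasedValues:
    def test_bellman_evaluation_with_fixed_structure(self):
        # state maxima (1, 0); action 0 commonly reaches state 0
        q2 = np.array([[1.0, 0.5], [0.0, 0.0]])
        np.testing.assert_allclose(
            model_based_values(q2, 0.7), [0.7, 0.3], atol=1e-12
        )

    def test_uniform_values_give_equal_stage1_values(self):
        q2 = np.full((2, 2), 0.37)
        np.testing.assert_allclose(model_based_values(q2, 0.7), [0.37, 0.37])

    def test_swapping_states_swaps_values(self):
        q2 = np.array([[0.9, 0.1], [0.4, 0.2]])
        forward = model_based_values(q2, 0.7)
        swapped = model_based_values(q2[::-1], 0.7)
        np.testing.assert_allclose(forward, swapped[::-1])


class TestChoiceProbabilities:
    def test_uninformative_softmax_is_uniform(self):
        probs = stage1_choice_probs(np.array([0.9, 0.1]), np.array([0.2, 0.8]),
                                    prev_choice1=0, params=UNIFORM)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_goal_directed_softmax_closed_form(self):
        params = ParameterSet(0.5, 0.5, 0.5, beta2=1.0, beta_hb=0.0,
                              beta_gd=1.0, p=0.0)
        probs = stage1_choice_probs(np.zeros(2), np.array([0.6, 0.4]),
                                    prev_choice1=None, params=params)
        expected = math.exp(0.6) / (math.exp(0.6) + math.exp(0.4))
        np.testing.assert_allclose(probs, [expected, 1 - expected], atol=1e-10)

    def test_extreme_perseveration_forces_repetition(self):
        params = ParameterSet(0.5, 0.5, 0.5, beta2=1.0, beta_hb=1.0,
                              beta_gd=1.0, p=500.0)
        probs = stage1_choice_probs(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                                    prev_choice1=0, params=params)
        assert probs[0] > 1 - 1e-12

    def test_stage2_closed_form(self):
        probs = stage2_choice_probs(np.array([0.75, 0.25]), beta2=2.0)
        expected = math.exp(1.5) / (math.exp(1.5) + math.exp(0.5))
        np.testing.assert_allclose(probs, [expected, 1 - expected], atol=1e-10)

    def test_stage2_probability_monotone_in_temperature(self):
        q = np.array([0.7, 0.3])
        p_high = [stage2_choice_probs(q, b)[0] for b in (0.0, 1.0, 3.0, 10.0)]
        assert p_high[0] == pytest.approx(0.5)
        assert all(a < b for a, b in zip(p_high, p_high[1:]))

    @given(params=params_strategy(),
           qmf=st.tuples(st.floats(0, 1), st.floats(0, 1)),
           qmb=st.tuples(st.floats(0, 1), st.floats(0, 1)),
           prev=st.sampled_from([None, 0, 1]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one_and_are_positive(self, params, qmf, qmb, prev):
        probs = stage1_choice_probs(np.array(qmf), np.array(qmb), prev, params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs > 0).all()


class TestTDUpdate:
    def test_hand_computed_single_step(self):
        # eligibility at (the open-interval limit of) 1
        params = ParameterSet(alpha1=0.5, alpha2=0.5, lam=1.0 - 1e-15,
                              beta2=1.0, beta_hb=1.0, beta_gd=1.0, p=0.0)
        state = AgentState(q_mf1=np.array([0.0, 0.0]),
                           q2=np.full((2, 2), 0.5), prev_choice1=None)
        new = td_update(state, choice1=0, state2=1, choice2=1, reward=1.0,
                        params=params)
        # delta1 = 0.5 - 0 -> q_mf1 = 0.25; delta2 = 0.5 -> q2 = 0.75,
        # q_mf1 += 0.5 * lam * 0.5 -> 0.5
        assert new.q_mf1[0] == pytest.approx(0.5)
        assert new.q2[1, 1] == pytest.approx(0.75)
        assert new.prev_choice1 == 0

    def test_zero_learning_rates_freeze_values(self):
        params = ParameterSet(alpha1=1e-300, alpha2=1e-300, lam=0.5,
                              beta2=1.0, beta_hb=1.0, beta_gd=1.0, p=0.0)
        state = AgentState()
        new = td_update(state, 1, 0, 1, 1.0, params)
        np.testing.assert_allclose(new.q_mf1, state.q_mf1, atol=1e-290)
        np.testing.assert_allclose(new.q2, state.q2, atol=1e-290)
        assert new.prev_choice1 == 1

    def test_zero_eligibility_ignores_reward_error(self):
        params = ParameterSet(alpha1=0.5, alpha2=0.5, lam=1e-300,
                              beta2=1.0, beta_hb=1.0, beta_gd=1.0, p=0.0)
        state = AgentState(q_mf1=np.array([0.2, 0.2]),
                           q2=np.full((2, 2), 0.5))
        new = td_update(state, 0, 0, 0, 1.0, params)
        # only delta1 = 0.5 - 0.2 reaches stage 1
        assert new.q_mf1[0] == pytest.approx(0.2 + 0.5 * 0.3)

    def test_unchosen_values_untouched(self, mid_params):
        state = AgentState(q_mf1=np.array([0.1, 0.9]),
                           q2=np.arange(4).reshape(2, 2) / 4.0)
        new = td_update(state, 0, 1, 0, 1.0, mid_params)
        assert new.q_mf1[1] == state.q_mf1[1]
        untouched = [(0, 0), (0, 1), (1, 1)]
        for s, a in untouched:
            assert new.q2[s, a] == state.q2[s, a]

    @given(params=params_strategy(), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q2_stays_in_unit_interval(self, params, seed):
        rng = np.random.default_rng(seed)
        state = AgentState()
        for _ in range(100):
            new = td_update(state, int(rng.integers(2)), int(rng.integers(2)),
                            int(rng.integers(2)), float(rng.integers(2)), params)
            assert (new.q2 >= 0).all() and (new.q2 <= 1).all()
            state = new


class TestSimulation:
    def test_fixed_seed_reproduces_session(self, short_config, mid_params):
        schedule = build_reward_schedule(short_config, 1)
        a = simulate_session(mid_params, short_config, schedule, 2)
        b = simulate_session(mid_params, short_config, schedule, 2)
        assert a.to_frame(short_config).equals(b.to_frame(short_config))

    def test_indifferent_agent_chooses_at_chance(self, default_config):
        schedule = build_reward_schedule(default_config, 3)
        config = TaskConfig(n_trials=201)
        sessions = [
            simulate_session(UNIFORM, config, schedule, 100 + s)
            for s in range(20)
        ]
        freq = np.mean([s.choice1.mean() for s in sessions])
        assert abs(freq - 0.5) < 0.03

    def test_greedy_goal_directed_agent_tracks_better_option(self):
        # one stage-2 arm is made permanently better; a near-greedy
        # goal-directed agent should mostly pick the action commonly
        # leading to that state
        config = TaskConfig(n_trials=300, walk_sd=0.0, break_after=())
        schedule = build_reward_schedule(config, 4)
        probs = schedule.probs.copy()
        probs[0] = 0.75   # state 0 / action 0 good
        probs[1] = 0.25
        probs[2] = 0.25   # state 1 poor
        probs[3] = 0.25
        forced = type(schedule)(probs=probs)
        params = ParameterSet(alpha1=0.7, alpha2=0.7, lam=0.5, beta2=8.0,
                              beta_hb=0.0, beta_gd=30.0, p=0.0)
        session = simulate_session(params, config, forced, 5)
        assert session.choice1[150:].mean() < 0.2  # mostly action 0


class TestSessionLikelihood:
    def test_uniform_policy_gives_2T_log2(self):
        session = random_session(37, seed=0)
        nll = session_neg_log_likelihood(session, UNIFORM)
        assert nll == pytest.approx(2 * 37 * math.log(2), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_agreement_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        session = random_session(25, seed=seed)
        params = ParameterSet(
            alpha1=float(rng.uniform(0.05, 0.95)),
            alpha2=float(rng.uniform(0.05, 0.95)),
            lam=float(rng.uniform(0.05, 0.95)),
            beta2=float(rng.uniform(0, 8)),
            beta_hb=float(rng.uniform(0, 8)),
            beta_gd=float(rng.uniform(0, 8)),
            p=float(rng.uniform(-2, 2)),
        )
        trials = [
            dict(choice1=int(c1), state2=int(s2), choice2=int(c2), reward=int(r))
            for c1, s2, c2, r in zip(session.choice1, session.state2,
                                     session.choice2, session.reward)
        ]
        expected = oracle_session_nll(trials, params.__dict__)
        assert session_neg_log_likelihood(session, params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_missing_trials_are_skipped(self, mid_params):
        session = random_session(20, seed=3)
        session.missing[5] = True
        session.missing[12] = True
        kept = [
            dict(choice1=int(c1), state2=int(s2), choice2=int(c2), reward=int(r))
            for i, (c1, s2, c2, r) in enumerate(
                zip(session.choice1, session.state2, session.choice2,
                    session.reward))
            if i not in (5, 12)
        ]
        expected = oracle_session_nll(kept, mid_params.__dict__)
        assert session_neg_log_likelihood(session, mid_params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_invariant_to_metadata_relabeling(self, mid_params):
        session = random_session(15, seed=4)
        relabeled = random_session(15, seed=4)
        relabeled.subject_id = "someone-else"
        relabeled.condition = "gaming"
        assert session_neg_log_likelihood(session, mid_params) == pytest.approx(
            session_neg_log_likelihood(relabeled, mid_params), abs=0
        )
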