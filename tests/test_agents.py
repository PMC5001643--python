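"""The hybrid agent: learning rules, valuation, choice, belief updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twostep as ts
from twostep.agents import (
    AgentParams,
    choice_probabilities,
    mb_values,
    mf_update,
    net_values,
    new_state,
    update_transition_belief,
)


def params(alpha=0.5, beta=5.0, lam=0.5, w=0.5, pi=0.0, rho=0.0):
    return AgentParams(alpha=alpha, beta=beta, lam=lam, w=w, pi=pi, rho=rho)


class TestAgentParams:
    @pytest.mark.parametrize("kw", [dict(alpha=1.2), dict(w=-0.1), dict(beta=-1),
                                    dict(lam=2.0)])
    def test_bounds_enforced(self, kw):
        with pytest.raises(ValueError):
            params(**kw)

    def test_round_trip(self):
        p = params(pi=0.2, rho=-0.1)
        assert AgentParams.from_dict(p.to_dict()) == p


class TestMfUpdate:
    def test_zero_learning_rate_changes_nothing(self, daw_task):
        state = new_state(daw_task)
        state.q_first[0, 0] = 0.3
        state.q_second[1, 1] = 0.7
        before_f, before_s = state.q_first.copy(), state.q_second.copy()
        mf_update(state, params(alpha=0.0), (0, 0), (1, 1), 1.0)
        assert np.array_equal(state.q_first, before_f)
        assert np.array_equal(state.q_second, before_s)

    def test_no_trace_blocks_first_stage_reward_credit(self, daw_task):
        """With lambda=0 the reward error reaches only the second stage."""
        state = new_state(daw_task)
        mf_update(state, params(alpha=1.0, lam=0.0), (0, 0), (1, 1), 1.0)
        assert state.q_second[1, 1] == 1.0
        assert state.q_first[0, 0] == 0.0

    def test_full_trace_credits_both_stages(self, daw_task):
        state = new_state(daw_task)
        mf_update(state, params(alpha=1.0, lam=1.0), (0, 0), (1, 1), 1.0)
        assert state.q_second[1, 1] == 1.0
        assert state.q_first[0, 0] == 1.0

    def test_intermediate_trace_scales_reward_credit(self, daw_task):
        state = new_state(daw_task)
        mf_update(state, params(alpha=0.5, lam=0.5), (0, 0), (1, 0), 1.0)
        # delta1 = 0; second stage: Q2 += 0.5*1; first stage += 0.5*1*0.5
        assert state.q_second[1, 0] == 0.5
        assert state.q_first[0, 0] == 0.25

    def test_binary_rewards_keep_values_in_unit_interval(self, daw_task, rng):
        """Convex-combination argument: Q stays in the hull of observed targets."""
        state = new_state(daw_task)
        p = params(alpha=0.7, lam=0.6)
        for _ in range(500):
            state.reset_eligibility()
            s2, a1, a2 = rng.integers(0, 2, size=3)
            mf_update(state, p, (0, a1), (s2, a2), float(rng.integers(0, 2)))
        assert np.all(state.q_first >= 0) and np.all(state.q_first <= 1)
        assert np.all(state.q_second >= 0) and np.all(state.q_second <= 1)


class TestMbValues:
    def test_bellman_backup_arithmetic(self, daw_task):
        state = new_state(daw_task)  # known beliefs: (0.7, 0.3) per action
        state.q_second[0] = [0.8, 0.1]
        state.q_second[1] = [0.4, 0.2]
        v = mb_values(state, 0)
        assert v[0] == pytest.approx(0.7 * 0.8 + 0.3 * 0.4)
        assert v[1] == pytest.approx(0.3 * 0.8 + 0.7 * 0.4)

    def test_uniform_belief_with_equal_maxima_is_flat(self, daw_task):
        state = new_state(daw_task, belief_mode="three_structure")
        state.q_second[:] = [[0.6, 0.1], [0.2, 0.6]]
        v = mb_values(state, 0)
        assert v[0] == v[1] == pytest.approx(0.6)

    def test_deterministic_belief_returns_mapped_state_maximum(self, doll_task):
        state = new_state(doll_task)
        state.q_second[0] = [0.9, 0.3]
        state.q_second[1] = [0.5, 0.2]
        v = mb_values(state, 0)
        assert v[0] == pytest.approx(0.9)
        assert v[1] == pytest.approx(0.5)


class TestNetValues:
    def test_endpoints_and_midpoint(self):
        q_mb, q_mf = np.array([0.68, 0.1]), np.array([0.2, 0.3])
        assert np.array_equal(net_values(q_mb, q_mf, 0.0), q_mf)
        assert np.array_equal(net_values(q_mb, q_mf, 1.0), q_mb)
        assert net_values(q_mb, q_mf, 0.5)[0] == pytest.approx(0.44)

    def test_w_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            net_values([1.0], [0.0], 1.5)


class TestChoiceProbabilities:
    def test_zero_inverse_temperature_is_uniform(self):
        p = choice_probabilities([3.0, -1.0], params(beta=0.0))
        assert np.allclose(p, [0.5, 0.5])

    def test_equal_values_split_evenly(self):
        p = choice_probabilities([0.4, 0.4], params(beta=7.0))
        assert np.allclose(p, [0.5, 0.5])

    def test_closed_form_two_action_softmax(self):
        p = choice_probabilities([1.0, 0.0], params(beta=5.0))
        expected = np.exp(5) / (np.exp(5) + 1)
        assert p[0] == pytest.approx(expected, rel=1e-12)

    def test_stickiness_biases_previous_choice_and_key(self):
        base = choice_probabilities([0.0, 0.0], params(beta=1.0))
        sticky = choice_probabilities(
            [0.0, 0.0], params(beta=1.0, pi=0.5), last_first_choice=1
        )
        assert sticky[1] > base[1]
        resp = choice_probabilities(
            [0.0, 0.0], params(beta=1.0, rho=0.5),
            last_key=0, action_keys=[1, 0],
        )
        assert resp[1] > resp[0]

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities([np.nan, 0.0], params())

    @given(
        v0=st.floats(-5, 5), v1=st.floats(-5, 5),
        shift=st.floats(-10, 10), beta=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalized_and_shift_invariant(self, v0, v1, shift, beta):
        p = choice_probabilities([v0, v1], params(beta=beta))
        q = choice_probabilities([v0 + shift, v1 + shift], params(beta=beta))
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(p, q, atol=1e-9)


class TestTransitionBeliefs:
    def test_known_mode_is_noop_at_veridical_matrix(self, daw_task):
        state = new_state(daw_task, belief_mode="known")
        before = state.belief_p0.copy()
        update_transition_belief(state, "known", (0, 0, 1))
        assert np.array_equal(state.belief_p0, before)
        assert np.allclose(before[0], [0.7, 0.3])

    def test_one_shot_reveals_full_mapping_for_start_state(self, doll_task):
        state = new_state(doll_task, belief_mode="one_shot")
        assert np.all(state.belief_p0 == 0.5)
        update_transition_belief(state, "one_shot", (0, 1, 0))
        assert state.belief_p0[0].tolist() == [0.0, 1.0]
        assert np.all(state.belief_p0[1] == 0.5)  # other start still unknown
        # later observations from the same start state change nothing
        update_transition_belief(state, "one_shot", (0, 0, 0))
        assert state.belief_p0[0].tolist() == [0.0, 1.0]

    def test_three_structure_prefers_flat_at_zero_counts(self, daw_task):
        state = new_state(daw_task, belief_mode="three_structure")
        assert np.all(state.belief_p0 == 0.5)

    def test_three_structure_selects_likelihood_winner(self, daw_task):
        """7 common / 3 rare observations pick the matching 70/30 structure,
        verified against an explicit multinomial likelihood comparison."""
        state = new_state(daw_task, belief_mode="three_structure")
        for _ in range(7):
            update_transition_belief(state, "three_structure", (0, 0, 0))
        for _ in range(3):
            update_transition_belief(state, "three_structure", (0, 0, 1))
        counts = state.transition_counts

        def loglik(p00, p01):
            p = np.array([[p00, 1 - p00], [p01, 1 - p01]])
            return (counts * np.log(p)).sum()

        candidates = {(0.5, 0.5): loglik(0.5, 0.5), (0.7, 0.3): loglik(0.7, 0.3),
                      (0.3, 0.7): loglik(0.3, 0.7)}
        best = max(candidates, key=candidates.get)
        assert best == (0.7, 0.3)
        assert state.belief_p0[0] == pytest.approx(best)

    def test_three_structure_requires_single_start_stochastic(self, doll_task):
        with pytest.raises(ValueError):
            new_state(doll_task, belief_mode="three_structure")


class TestRunSession:
    @pytest.mark.parametrize("preset,belief,w", [
        ("daw", "known", 0.5),
        ("daw", "three_structure", 0.3),
        ("doll", "one_shot", 0.8),
        ("novel", "known", 1.0),
        ("novel_human", "one_shot", 0.5),
        ("dezfouli", "known", 0.0),
        ("akam", "known", 0.7),
        ("doll_stochastic_hybrid", "known", 0.5),
    ])
    def test_compiled_kernel_matches_python_reference(self, preset, belief, w):
        task = ts.make_task(preset)
        sched = ts.make_schedule(task, seed=100)
        p = params(alpha=0.6, beta=3.0, lam=0.4, w=w, pi=0.1, rho=-0.2)
        fast = ts.run_session(task, sched, p, belief_mode=belief, seed=55)
        slow = ts.run_session(task, sched, p, belief_mode=belief, seed=55,
                              engine="python")
        assert fast.table.equals(slow.table)

    def test_seed_reproducibility(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=4)
        p = params()
        a = ts.run_session(daw_task, sched, p, seed=9)
        b = ts.run_session(daw_task, sched, p, seed=9)
        assert a.table.equals(b.table)

    def test_model_based_agent_exploits_scalar_task(self, novel_task):
        """A pure planner with known transitions and moderate choice noise
        (noise buys the exploration value tracking needs) earns clearly
        more than the schedule average."""
        excess = 0.0
        for i in range(10):
            sched = ts.make_schedule(novel_task, seed=300 + i)
            p = params(alpha=1.0, beta=5.0, lam=1.0, w=1.0)
            sess = ts.run_session(novel_task, sched, p, seed=400 + i)
            excess += sess.reward_rate() - sched.values.mean()
        assert excess / 10 > 0.05

    def test_schedule_task_arm_mismatch_rejected(self, daw_task):
        sched = ts.RewardSchedule(np.full((201, 2), 0.5))
        with pytest.raises(ValueError, match="arms"):
            ts.run_session(daw_task, sched, params(), seed=0)

    def test_short_schedule_rejected(self, daw_task):
        sched = ts.RewardSchedule(np.full((50, 4), 0.5))
        with pytest.raises(ValueError, match="schedule"):
            ts.run_session(daw_task, sched, params(), seed=0)
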