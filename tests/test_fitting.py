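"""MAP fitting: likelihood, priors, restarts, model comparison, recovery."""

import numpy as np
import pytest
from scipy import stats

import twostep as ts
from twostep.agents import (
    choice_probabilities,
    mb_values,
    mf_update,
    net_values,
    new_state,
    update_transition_belief,
)
from twostep.fitting import (
    ModelVariant,
    PriorSpec,
    compare_models,
    fit_session,
    parameter_recovery,
    session_log_likelihood,
)


def replay_log_likelihood(params, session, task, belief_mode):
    """Independent likelihood oracle: replay the session through the
    plain-Python agent operations, accumulating log choice probabilities."""
    state = new_state(task, belief_mode)
    ll = 0.0
    for _, row in session.table.iterrows():
        if row.timeout:
            state.last_first_choice = None
            state.last_key = None
            continue
        s, a1, k1 = int(row.start_state), int(row.choice1), int(row.key1)
        flip = a1 ^ k1
        state.reset_eligibility()
        q_net = net_values(mb_values(state, s), state.q_first[s], params.w)
        p = choice_probabilities(
            q_net, params, state.last_first_choice, state.last_key,
            action_keys=[flip, 1 ^ flip],
        )
        ll += np.log(p[a1])
        s2, a2 = int(row.state2), int(row.choice2)
        if task.n_second_actions == 2:
            p2 = choice_probabilities(state.q_second[s2], params)
            ll += np.log(p2[a2])
        mf_update(state, params, (s, a1), (s2, a2), float(row.reward))
        update_transition_belief(state, belief_mode, (s, a1, s2))
        state.last_first_choice = a1
        state.last_key = k1
    return ll


class TestLogLikelihood:
    def test_uniform_policy_closed_form(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=1)
        sess = ts.run_session(daw_task, sched, ts.AgentParams(0.5, 5, 0.5, 0.5), seed=2)
        p0 = ts.AgentParams(0.5, 0.0, 0.5, 0.5)
        ll = session_log_likelihood(p0, sess, daw_task)
        assert ll == pytest.approx(2 * len(sess) * np.log(0.5))

    def test_forced_second_stage_contributes_nothing(self, novel_human_task):
        """Single-action second stages add no choice likelihood, so the
        beta = 0 total is one log(1/2) per trial, not two."""
        sched = ts.make_schedule(novel_human_task, seed=3)
        sess = ts.run_session(
            novel_human_task, sched, ts.AgentParams(0.5, 2, 0.5, 0.5),
            belief_mode="one_shot", seed=4,
        )
        ll = session_log_likelihood(
            ts.AgentParams(0.5, 0.0, 0.5, 0.5), sess, novel_human_task
        )
        assert ll == pytest.approx(len(sess) * np.log(0.5))

    @pytest.mark.parametrize("preset,belief", [
        ("daw", "three_structure"),
        ("doll", "one_shot"),
        ("novel_human", "one_shot"),
    ])
    def test_matches_python_replay_oracle(self, preset, belief):
        task = ts.make_task(preset)
        sched = ts.make_schedule(task, seed=11)
        gen = ts.AgentParams(0.6, 2.5, 0.4, 0.7, pi=0.15, rho=-0.1)
        sess = ts.run_session(task, sched, gen, belief_mode=belief, seed=12)
        probe = ts.AgentParams(0.3, 1.8, 0.6, 0.4, pi=-0.2, rho=0.3)
        fast = session_log_likelihood(probe, sess, task, belief)
        slow = replay_log_likelihood(probe, sess, task, belief)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_timeouts_skip_likelihood_but_not_learning_state(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=21)
        sess = ts.run_session(daw_task, sched, ts.AgentParams(0.5, 3, 0.5, 0.5), seed=22)
        flagged = ts.inject_timeouts(sess, 0.1, seed=23)
        probe = ts.AgentParams(0.4, 2.0, 0.5, 0.5)
        fast = session_log_likelihood(probe, flagged, daw_task)
        slow = replay_log_likelihood(probe, flagged, daw_task, "three_structure")
        assert fast == pytest.approx(slow, rel=1e-10)
        assert np.isfinite(fast)

    def test_key_relabeling_invariance_without_response_stickiness(self, daw_task):
        """With rho = 0 the likelihood ignores which physical key carried
        each action."""
        sched = ts.make_schedule(daw_task, seed=31)
        sess = ts.run_session(daw_task, sched, ts.AgentParams(0.5, 3, 0.5, 0.5), seed=32)
        flipped = ts.SessionData(
            sess.table.assign(key1=1 - sess.table["key1"]), schedule=sess.schedule
        )
        probe = ts.AgentParams(0.4, 2.0, 0.5, 0.5, pi=0.3, rho=0.0)
        assert session_log_likelihood(probe, sess, daw_task) == pytest.approx(
            session_log_likelihood(probe, flipped, daw_task)
        )


class TestPriors:
    def test_log_densities_match_scipy(self):
        prior = PriorSpec()
        for b in (0.1, 1.0, 4.2, 15.0):
            assert prior.log_prior("beta", b) == pytest.approx(
                stats.gamma.logpdf(b, a=4.82, scale=0.88), rel=1e-10
            )
        for x in (-2.0, 0.15, 1.0):
            assert prior.log_prior("pi", x) == pytest.approx(
                stats.norm.logpdf(x, 0.15, 1.42), rel=1e-10
            )
        assert prior.log_prior("alpha", 0.3) == 0.0

    def test_map_equals_posterior_decomposition(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=41)
        sess = ts.run_session(daw_task, sched, ts.AgentParams(0.5, 3, 0.5, 0.5), seed=42)
        fit = fit_session(sess, daw_task, n_restarts=3, seed=43)
        prior = PriorSpec()
        lp = sum(
            prior.log_prior(n, getattr(fit.params, n))
            for n in fit.variant.free_params
        )
        assert fit.log_posterior == pytest.approx(fit.log_likelihood + lp, abs=1e-6)


@pytest.fixture(scope="module")
def daw_session(daw_task):
    sched = ts.make_schedule(daw_task, seed=51)
    return ts.run_session(
        daw_task, sched, ts.AgentParams(0.4, 4.0, 0.5, 0.6, pi=0.2, rho=0.05),
        belief_mode="three_structure", seed=52,
    )


class TestFitSession:
    def test_estimates_respect_bounds(self, daw_task, daw_session):
        fit = fit_session(daw_session, daw_task, n_restarts=5, seed=1)
        p = fit.params
        assert 0 <= p.alpha <= 1 and 0 <= p.lam <= 1 and 0 <= p.w <= 1
        assert p.beta >= 0

    def test_information_criteria_definitions(self, daw_task, daw_session):
        fit = fit_session(daw_session, daw_task, n_restarts=3, seed=2)
        assert fit.bic == pytest.approx(
            -2 * fit.log_likelihood + fit.n_params * np.log(fit.n_obs)
        )
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_params)
        assert fit.n_obs == 2 * len(daw_session)

    def test_more_restarts_never_worse_on_same_seed_stream(self, daw_task, daw_session):
        few = fit_session(daw_session, daw_task, n_restarts=3, seed=7)
        many = fit_session(daw_session, daw_task, n_restarts=10, seed=7)
        assert many.log_posterior >= few.log_posterior - 1e-9

    def test_excessive_timeouts_trigger_exclusion(self, daw_task, daw_session):
        bad = ts.inject_timeouts(daw_session, 0.4, seed=3)
        if bad.n_timeouts > 0.2 * len(bad):
            with pytest.raises(ValueError, match="excluded"):
                fit_session(bad, daw_task, n_restarts=2, seed=4)

    def test_long_session_recovers_pure_model_based_weight(self, novel_human_task):
        """Consistency: a high-beta w = 1 agent on the planning-friendly
        task is identified as strongly model-based from 1000 trials."""
        sched = ts.make_schedule(novel_human_task, seed=61, n_trials=1000)
        sess = ts.run_session(
            novel_human_task, sched, ts.AgentParams(0.7, 5.0, 0.5, 1.0),
            n_trials=1000, belief_mode="one_shot", seed=62,
        )
        variant = ModelVariant("free", include_pi=False, include_rho=True)
        fit = fit_session(sess, novel_human_task, variant=variant,
                          n_restarts=8, seed=63)
        assert fit.params.w > 0.9


class TestCompareModels:
    def test_nested_variants_never_beat_the_hybrid_likelihood(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=71)
        sess = ts.run_session(
            daw_task, sched, ts.AgentParams(0.5, 4.0, 0.5, 0.5),
            belief_mode="three_structure", seed=72,
        )
        table = compare_models(sess, daw_task, n_restarts=6, seed=73)
        table = table.set_index("variant")
        hybrid_ll = table.loc["hybrid_pirho", "log_lik"]
        assert table.loc["pure_mf_pirho", "log_lik"] <= hybrid_ll + 1e-6
        assert table.loc["pure_mb_pirho", "log_lik"] <= hybrid_ll + 1e-6

    def test_parameter_counts_track_free_parameters(self, daw_task):
        sched = ts.make_schedule(daw_task, seed=81)
        sess = ts.run_session(daw_task, sched, ts.AgentParams(0.5, 3, 0.5, 0.5), seed=82)
        variants = [
            ModelVariant("free", True, True),
            ModelVariant("mf", True, True),
            ModelVariant("free", False, False),
        ]
        table = compare_models(sess, daw_task, variants=variants,
                               n_restarts=2, seed=83)
        assert table["k"].tolist() == [6, 5, 4]


class TestParameterRecovery:
    def test_noiseless_limit_recovers_w_strongly(self, novel_human_task):
        """High-beta agents on long deterministic-transition sessions:
        w must correlate with truth far above chance."""
        variant = ModelVariant("free", include_pi=False, include_rho=True)

        def sampler(rng):
            return ts.AgentParams(
                alpha=rng.uniform(0.3, 1.0), beta=rng.uniform(3, 8),
                lam=rng.uniform(0, 1), w=rng.uniform(0, 1),
                rho=rng.normal(0.15, 0.5),
            )

        summary, detail = parameter_recovery(
            novel_human_task, n_agents=20, n_trials=600, param_sampler=sampler,
            seed=5, n_restarts=6, variant=variant,
        )
        r_w = summary.set_index("parameter").loc["w", "r"]
        assert r_w > 0.9
        est_cols = [c for c in detail.columns if c.startswith("est_")]
        assert (detail["est_alpha"].between(0, 1)).all()
        assert (detail["est_w"].between(0, 1)).all()
        assert len(est_cols) == len(variant.free_params)
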