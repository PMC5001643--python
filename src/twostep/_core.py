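"""Compiled inner loops for session simulation and likelihood evaluation.

The trade-off analyses simulate millions of 201-trial sessions and the
fitting routines evaluate the session likelihood thousands of times per
subject, so the per-trial loop is compiled with numba.  All randomness
enters through pre-drawn uniform variates (one ``(n_trials, 6)`` block
per session: start state, key layout, first choice, transition, second
choice, outcome), which keeps the kernels deterministic functions of
their inputs and keeps seeding at the numpy ``Generator`` level.

A pure-Python twin of the simulation loop lives in ``agents.py`` and is
held equal to the compiled path by the test suite.

Belief modes: 0 = known (veridical transition model), 1 = one-shot
inference of a deterministic mapping, 2 = selection among the flat and
the two symmetric 70/30 structures by maximum likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BELIEF_KNOWN = 0
BELIEF_ONE_SHOT = 1
BELIEF_THREE_STRUCTURE = 2

# clip softmax logits so that log choice probabilities stay finite
# (exp(30) ~ 1e13: the minority probability bottoms out near 1e-13)
_EXP_CLIP = 30.0


@njit(cache=True)
def _binary_softmax_p0(v0, v1, beta):
    """P(action 0) under a two-action softmax with inverse temperature beta."""
    d = beta * (v1 - v0)
    if d > _EXP_CLIP:
        d = _EXP_CLIP
    elif d < -_EXP_CLIP:
        d = -_EXP_CLIP
    return 1.0 / (1.0 + np.exp(d))


@njit(cache=True)
def _init_belief_p0(n_start, belief_mode, transition_det, common_prob, common_dest):
    """Initial P(second state 0 | start, action) per belief mode."""
    p0 = np.empty((n_start, 2))
    for s in range(n_start):
        for a in range(2):
            if belief_mode == BELIEF_KNOWN:
                cp = 1.0 if transition_det else common_prob
                p0[s, a] = cp if common_dest[s, a] == 0 else 1.0 - cp
            else:
                p0[s, a] = 0.5
    return p0


@njit(cache=True)
def _select_structure(counts, common_prob):
    """Maximum-likelihood pick among flat / 70-30 / 30-70 structures.

    ``counts[a, s]`` are observed (first action, second state) tallies.
    The flat structure wins ties, so with no data the belief is uniform.
    Returns P(second state 0 | action) for the two actions.
    """
    n = counts[0, 0] + counts[0, 1] + counts[1, 0] + counts[1, 1]
    lp_c = np.log(common_prob)
    lp_r = np.log(1.0 - common_prob)
    ll_flat = n * np.log(0.5)
    # structure A: action 0 commonly -> state 0, action 1 -> state 1
    n_a = counts[0, 0] + counts[1, 1]
    ll_a = n_a * lp_c + (n - n_a) * lp_r
    ll_b = (n - n_a) * lp_c + n_a * lp_r
    best = ll_flat
    p00 = 0.5
    p01 = 0.5
    if ll_a > best:
        best = ll_a
        p00 = common_prob
        p01 = 1.0 - common_prob
    if ll_b > best:
        p00 = 1.0 - common_prob
        p01 = common_prob
    return p00, p01


@njit(cache=True)
def _simulate(
    values,
    outcome_scalar,
    n_start,
    n_sec,
    transition_det,
    common_prob,
    common_dest,
    alpha,
    beta,
    lam,
    w,
    pi,
    rho,
    belief_mode,
    u,
    out_start,
    out_c1,
    out_key1,
    out_common,
    out_s2,
    out_c2,
    out_reward,
):
    """Simulate one session, writing the per-trial record into ``out_*``."""
    n_trials = u.shape[0]
    q1 = np.zeros((n_start, 2))
    q2 = np.zeros((2, n_sec))
    belief_p0 = _init_belief_p0(
        n_start, belief_mode, transition_det, common_prob, common_dest
    )
    seen = np.zeros(n_start, dtype=np.int64)
    counts = np.zeros((2, 2))
    last_c1 = -1
    last_key = -1

    for t in range(n_trials):
        s = 0
        if n_start == 2 and u[t, 0] >= 0.5:
            s = 1
        flip = 1 if u[t, 1] >= 0.5 else 0

        # model-based first-stage values via one-step Bellman backup
        max0 = q2[0, 0]
        max1 = q2[1, 0]
        if n_sec == 2:
            if q2[0, 1] > max0:
                max0 = q2[0, 1]
            if q2[1, 1] > max1:
                max1 = q2[1, 1]
        v = np.empty(2)
        for a in range(2):
            p0 = belief_p0[s, a]
            mb = p0 * max0 + (1.0 - p0) * max1
            v[a] = w * mb + (1.0 - w) * q1[s, a]
            if a == last_c1:
                v[a] += pi
            if (a ^ flip) == last_key:
                v[a] += rho
        p_a0 = _binary_softmax_p0(v[0], v[1], beta)
        c1 = 0 if u[t, 2] < p_a0 else 1

        dest = common_dest[s, c1]
        if transition_det:
            s2 = dest
            common = 1
        else:
            if u[t, 3] < common_prob:
                s2 = dest
                common = 1
            else:
                s2 = 1 - dest
                common = 0

        if n_sec == 2:
            p_b0 = _binary_softmax_p0(q2[s2, 0], q2[s2, 1], beta)
            c2 = 0 if u[t, 4] < p_b0 else 1
        else:
            c2 = 0

        sched = values[t, s2 * n_sec + c2]
        if outcome_scalar:
            r = sched
        else:
            r = 1.0 if u[t, 5] < sched else 0.0

        # SARSA(lambda): eligibilities reset each trial; the first-stage
        # pair is updated at the second stage with delta1, then receives
        # the reward prediction error delta2 down-weighted by lambda.
        delta1 = q2[s2, c2] - q1[s, c1]
        q1[s, c1] += alpha * delta1
        delta2 = r - q2[s2, c2]
        q2[s2, c2] += alpha * delta2
        q1[s, c1] += alpha * delta2 * lam

        if belief_mode == BELIEF_ONE_SHOT:
            if seen[s] == 0:
                if s2 == 0:
                    belief_p0[s, c1] = 1.0
                    belief_p0[s, 1 - c1] = 0.0
                else:
                    belief_p0[s, c1] = 0.0
                    belief_p0[s, 1 - c1] = 1.0
                seen[s] = 1
        elif belief_mode == BELIEF_THREE_STRUCTURE:
            counts[c1, s2] += 1.0
            p00, p01 = _select_structure(counts, common_prob)
            belief_p0[0, 0] = p00
            belief_p0[0, 1] = p01

        last_c1 = c1
        last_key = c1 ^ flip

        out_start[t] = s
        out_c1[t] = c1
        out_key1[t] = last_key
        out_common[t] = common
        out_s2[t] = s2
        out_c2[t] = c2
        out_reward[t] = r


@njit(cache=True)
def _session_mean_reward(
    values,
    outcome_scalar,
    n_start,
    n_sec,
    transition_det,
    common_prob,
    common_dest,
    alpha,
    beta,
    lam,
    w,
    belief_mode,
    u,
    scratch_i,
    scratch_f,
):
    """Reward rate of one simulated session (scratch buffers reused)."""
    n_trials = u.shape[0]
    _simulate(
        values, outcome_scalar, n_start, n_sec, transition_det, common_prob,
        common_dest, alpha, beta, lam, w, 0.0, 0.0, belief_mode, u,
        scratch_i[0], scratch_i[1], scratch_i[2], scratch_i[3], scratch_i[4],
        scratch_i[5], scratch_f,
    )
    total = 0.0
    for t in range(n_trials):
        total += scratch_f[t]
    return total / n_trials


@njit(cache=True)
def _reward_rates_batch(
    values,
    outcome_scalar,
    n_start,
    n_sec,
    transition_det,
    common_prob,
    common_dest,
    alphas,
    betas,
    lams,
    ws,
    belief_mode,
    u,
):
    """Reward rates for many parameterizations on one shared schedule.

    ``u`` has shape (n_combos, n_trials, 6); combo ``i`` runs with
    ``(alphas[i], betas[i], lams[i], ws[i])``.
    """
    n_combos = u.shape[0]
    n_trials = u.shape[1]
    out = np.empty(n_combos)
    scratch_i = np.zeros((6, n_trials), dtype=np.int64)
    scratch_f = np.zeros(n_trials)
    for i in range(n_combos):
        out[i] = _session_mean_reward(
            values, outcome_scalar, n_start, n_sec, transition_det, common_prob,
            common_dest, alphas[i], betas[i], lams[i], ws[i], belief_mode,
            u[i], scratch_i, scratch_f,
        )
    return out


@njit(cache=True)
def _log_likelihood(
    n_start,
    n_sec,
    transition_det,
    common_prob,
    common_dest,
    alpha,
    beta,
    lam,
    w,
    pi,
    rho,
    belief_mode,
    start,
    c1,
    key1,
    s2,
    c2,
    reward,
    timeout,
    second_stage_choice,
):
    """Log likelihood of an observed session under the hybrid model.

    The agent's learning is rolled forward on the participant's actual
    choices and outcomes.  Timed-out trials contribute no likelihood and
    trigger no value update, and clear the stickiness reference, but do
    not otherwise reset the agent.  ``second_stage_choice`` controls
    whether second-stage choices enter the likelihood (they do only when
    the task affords a real second-stage choice).
    """
    n_trials = start.shape[0]
    q1 = np.zeros((n_start, 2))
    q2 = np.zeros((2, n_sec))
    belief_p0 = _init_belief_p0(
        n_start, belief_mode, transition_det, common_prob, common_dest
    )
    seen = np.zeros(n_start, dtype=np.int64)
    counts = np.zeros((2, 2))
    last_c1 = -1
    last_key = -1
    ll = 0.0

    for t in range(n_trials):
        if timeout[t] != 0:
            last_c1 = -1
            last_key = -1
            continue
        s = start[t]
        a1 = c1[t]
        k1 = key1[t]
        flip = a1 ^ k1  # key layout on this trial: key(a) = a ^ flip

        max0 = q2[0, 0]
        max1 = q2[1, 0]
        if n_sec == 2:
            if q2[0, 1] > max0:
                max0 = q2[0, 1]
            if q2[1, 1] > max1:
                max1 = q2[1, 1]
        v = np.empty(2)
        for a in range(2):
            p0 = belief_p0[s, a]
            mb = p0 * max0 + (1.0 - p0) * max1
            v[a] = w * mb + (1.0 - w) * q1[s, a]
            if a == last_c1:
                v[a] += pi
            if (a ^ flip) == last_key:
                v[a] += rho
        p_a0 = _binary_softmax_p0(v[0], v[1], beta)
        ll += np.log(p_a0 if a1 == 0 else 1.0 - p_a0)

        st2 = s2[t]
        a2 = c2[t]
        if second_stage_choice and n_sec == 2:
            p_b0 = _binary_softmax_p0(q2[st2, 0], q2[st2, 1], beta)
            ll += np.log(p_b0 if a2 == 0 else 1.0 - p_b0)

        r = reward[t]
        delta1 = q2[st2, a2] - q1[s, a1]
        q1[s, a1] += alpha * delta1
        delta2 = r - q2[st2, a2]
        q2[st2, a2] += alpha * delta2
        q1[s, a1] += alpha * delta2 * lam

        if belief_mode == BELIEF_ONE_SHOT:
            if seen[s] == 0:
                if st2 == 0:
                    belief_p0[s, a1] = 1.0
                    belief_p0[s, 1 - a1] = 0.0
                else:
                    belief_p0[s, a1] = 0.0
                    belief_p0[s, 1 - a1] = 1.0
                seen[s] = 1
        elif belief_mode == BELIEF_THREE_STRUCTURE:
            counts[a1, st2] += 1.0
            p00, p01 = _select_structure(counts, common_prob)
            belief_p0[0, 0] = p00
            belief_p0[0, 1] = p01

        last_c1 = a1
        last_key = k1

    return ll
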