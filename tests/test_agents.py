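"""Reward transforms, update rules and per-trial model dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ierl import agents, build_design, simulate_agent
from ierl._likelihood import trial_log_likelihoods
from ierl.agents import (
    AgentState,
    delta_update,
    hybrid_outcome_transform,
    intrinsic_reward,
    intrinsically_enhanced_reward,
    model_step,
    param_names,
    range_adapted_reward,
    softmax_policy,
)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,beta,expected",
    [
        ([0.0, 0.0], 7.3, [0.5, 0.5]),
        ([1.0, -2.0, 0.4], 0.0, [1 / 3] * 3),
        ([1.0, 0.0], np.log(3), [0.75, 0.25]),
    ],
)
def test_softmax_examples(values, beta, expected):
    assert np.allclose(softmax_policy(values, beta), expected)


@settings(derandomize=True, max_examples=50)
@given(
    vals=st.lists(st.floats(-10, 10), min_size=2, max_size=3),
    beta=st.floats(0, 50),
    shift=st.floats(-5, 5),
)
def test_softmax_properties(vals, beta, shift):
    p = softmax_policy(vals, beta)
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p > 0).all()
    shifted = softmax_policy([v + shift for v in vals], beta)
    assert np.allclose(p, shifted, atol=1e-9)


def test_softmax_errors():
    with pytest.raises(ValueError):
        softmax_policy([], 1.0)
    with pytest.raises(ValueError):
        softmax_policy([0, 1], -0.1)


@pytest.mark.parametrize(
    "q,outcome,alpha,expected",
    [(0.0, 1.0, 1.0, 1.0), (0.5, 1.0, 0.2, 0.6), (0.7, -4.0, 0.0, 0.7)],
)
def test_delta_update(q, outcome, alpha, expected):
    assert delta_update(q, outcome, alpha) == pytest.approx(expected)


@pytest.mark.parametrize(
    "r,lo,hi,z,expected",
    [(10, 0, 10, 1, 1.0), (0, 0, 10, 1, 0.0), (50, 14, 86, 2, 0.25)],
)
def test_range_adapted_reward(r, lo, hi, z, expected):
    assert range_adapted_reward(r, lo, hi, z) == pytest.approx(expected)


@settings(derandomize=True, max_examples=50)
@given(
    r=st.floats(-20, 20),
    z=st.floats(0.1, 5),
)
def test_range_adapted_bounds(r, z):
    rr = range_adapted_reward(r, -1.0, 2.0, z)
    assert 0.0 <= rr <= 1.0


def test_range_adapted_degenerate():
    with pytest.raises(ValueError):
        range_adapted_reward(1.0, 2.0, 2.0)


def test_intrinsic_reward_rules():
    # complete feedback: best revealed outcome wins
    assert intrinsic_reward(1.0, [0.0], context_r_max=1.0) == 1
    assert intrinsic_reward(0.0, [1.0], context_r_max=1.0) == 0
    # loss avoidance: got the least-bad outcome
    assert intrinsic_reward(-1.0, [0.0], context_r_max=0.0) == 0
    assert intrinsic_reward(0.0, [-1.0], context_r_max=0.0) == 1
    # trinary: middle outcome is not the trial's best
    assert intrinsic_reward(51.0, [13.2, 84.9], context_r_max=86.0) == 0
    assert intrinsic_reward(84.9, [13.2, 51.0], context_r_max=86.0) == 1
    # ties grant the goal to both options
    assert intrinsic_reward(0.0, [0.0], context_r_max=1.0) == 1
    # partial feedback: compare to the known context maximum
    assert intrinsic_reward(1.0, [], context_r_max=1.0) == 1
    assert intrinsic_reward(0.0, [], context_r_max=1.0) == 0


def test_complete_feedback_exactly_one_goal(m22_records):
    for rec in m22_records:
        if rec.trial.phase != "learning":
            continue
        outs = [rec.outcomes[o] for o in rec.trial.options]
        irs = [
            intrinsic_reward(outs[i], outs[:i] + outs[i + 1 :], 86.0)
            for i in range(len(outs))
        ]
        assert sum(irs) == 1  # gaussian outcomes never tie


@pytest.mark.parametrize(
    "r,ir,omega,expected",
    [(0.4, 1, 0.0, 0.4), (0.0, 1, 1.0, 1.0), (0.0, 1, 0.5, 0.5)],
)
def test_intrinsically_enhanced_reward(r, ir, omega, expected):
    assert intrinsically_enhanced_reward(r, ir, omega) == pytest.approx(expected)


@pytest.mark.parametrize(
    "r,d,expected",
    [(-1.0, 0.0, 0.0), (1.0, 0.5, 0.5), (0.0, 0.8, 0.0), (-0.5, 1.0, -1.0)],
)
def test_hybrid_outcome_transform(r, d, expected):
    assert hybrid_outcome_transform(r, d, has_losses=True) == pytest.approx(expected)
    assert hybrid_outcome_transform(r, d, has_losses=False) == r


# ---------------------------------------------------------------------------
# one-trial dispatch and reduction identities
# ---------------------------------------------------------------------------


def _replay_ll(model_id, params, records, design):
    """Pure-Python per-trial log likelihoods via model_step."""
    state = AgentState()
    out = []
    for rec in records:
        if rec.trial.phase == "rating":
            continue
        probs, state = model_step(model_id, state, rec, params, design)
        out.append(np.log(probs[rec.trial.options.index(rec.choice)]))
    return np.array(out)


def test_unknown_model_errors(m22, m22_records):
    with pytest.raises(ValueError, match="unknown model"):
        model_step("qlearn", AgentState(), m22_records[0], {}, m22)
    with pytest.raises(KeyError, match="beta_learn"):
        model_step("unbiased", AgentState(), m22_records[0], {"alpha_c": 0.5}, m22)


def test_param_names_follow_design(m22, b21_cci, b18_partial):
    assert param_names("intrinsic", m22) == (
        "alpha_c", "alpha_u", "beta_learn", "beta_test", "omega_learn",
    )
    # B21 complete/complete variant: counterfactual + test feedback
    assert "omega_test" in param_names("intrinsic", b21_cci)
    # loss designs split the chosen-option learning rate
    b18_2 = build_design("B18", "2")
    assert {"alpha_gains", "alpha_loss"} <= set(param_names("range_z", b18_2))
    assert "alpha_u" not in param_names("unbiased", b18_partial)
    assert param_names("wsls", m22) == ("beta_learn", "beta_test")
    assert "d" in param_names("hybrid_ac", b18_2)
    assert "d" not in param_names("hybrid_ac", m22)


def test_reduction_identities(m22, m22_records):
    """Exact per-trial equalities between nested model variants."""
    base = {"alpha_c": 0.35, "alpha_u": 0.2, "beta_learn": 5.0, "beta_test": 4.0}
    ll_unbiased = _replay_ll("unbiased", base, m22_records, m22)
    # intrinsic with omega=0 is the unbiased learner
    ll_intr = _replay_ll("intrinsic", {**base, "omega_learn": 0.0}, m22_records, m22)
    assert np.array_equal(ll_intr, ll_unbiased)
    # range^z with z=1 is the linear range model
    ll_rz = _replay_ll("range_z", {**base, "z": 1.0}, m22_records, m22)
    ll_r = _replay_ll("range", base, m22_records, m22)
    assert np.array_equal(ll_rz, ll_r)
    # WSLS is the unbiased learner with unit learning rates
    ll_wsls = _replay_ll("wsls", {"beta_learn": 5.0, "beta_test": 4.0}, m22_records, m22)
    ll_unit = _replay_ll(
        "unbiased",
        {"alpha_c": 1.0, "alpha_u": 1.0, "beta_learn": 5.0, "beta_test": 4.0},
        m22_records,
        m22,
    )
    assert np.array_equal(ll_wsls, ll_unit)


def test_hybrid_h_limits(m22, m22_records):
    hy = {"alpha_c": 0.35, "alpha_u": 0.2, "alpha_critic": 0.4,
          "alpha_actor": 0.3, "h": 1.0, "beta": 5.0}
    ll_h1 = _replay_ll("hybrid_ac", hy, m22_records, m22)
    ll_q = _replay_ll(
        "unbiased",
        {"alpha_c": 0.35, "alpha_u": 0.2, "beta_learn": 5.0, "beta_test": 5.0},
        m22_records,
        m22,
    )
    assert np.allclose(ll_h1, ll_q, atol=1e-12)
    # h=0: policy driven by actor weights only (insensitive to alpha_c)
    hy0 = {**hy, "h": 0.0}
    hy0b = {**hy0, "alpha_c": 0.9}
    assert np.array_equal(
        _replay_ll("hybrid_ac", hy0, m22_records, m22),
        _replay_ll("hybrid_ac", hy0b, m22_records, m22),
    )


def test_hybrid_weight_normalization(m22, m22_records):
    state = AgentState()
    params = {"alpha_c": 0.3, "alpha_u": 0.2, "alpha_critic": 0.5,
              "alpha_actor": 0.4, "h": 0.5, "beta": 3.0}
    for rec in m22_records[:40]:
        _, state = model_step("hybrid_ac", state, rec, params, m22)
        ctx = m22.context(rec.trial.context_id)
        total = sum(abs(state.W.get(o, 0.0)) for o in ctx.option_ids)
        if any(state.W.get(o, 0.0) != 0 for o in ctx.option_ids):
            assert total == pytest.approx(1.0)


@pytest.mark.parametrize("model_id,extra", [
    ("unbiased", {}),
    ("wsls", None),
    ("range", {}),
    ("range_z", {"z": 1.7}),
    ("intrinsic", {"omega_learn": 0.6}),
    ("hybrid_ac", None),
])
def test_compiled_kernel_matches_reference(model_id, extra, m22):
    """The numba likelihood kernel agrees with the pure-Python replay."""
    if model_id == "wsls":
        params = {"beta_learn": 3.0, "beta_test": 2.0}
    elif model_id == "hybrid_ac":
        params = {"alpha_c": 0.3, "alpha_u": 0.25, "alpha_critic": 0.4,
                  "alpha_actor": 0.35, "h": 0.4, "beta": 4.0}
    else:
        params = {"alpha_c": 0.3, "alpha_u": 0.25, "beta_learn": 5.0,
                  "beta_test": 4.0, **extra}
    recs = simulate_agent(model_id, params, m22, seed=99)
    ref = _replay_ll(model_id, params, recs, m22)
    fast = trial_log_likelihoods(model_id, params, recs, m22)
    assert np.allclose(ref, fast, atol=1e-12)


def test_compiled_kernel_matches_reference_loss_design():
    d = build_design("B18", "2")
    params = {"alpha_gains": 0.4, "alpha_loss": 0.25, "alpha_u": 0.2,
              "beta_learn": 4.0, "beta_test": 3.0, "omega_learn": 0.5}
    recs = simulate_agent("intrinsic", params, d, seed=5)
    assert np.allclose(
        _replay_ll("intrinsic", params, recs, d),
        trial_log_likelihoods("intrinsic", params, recs, d),
        atol=1e-12,
    )


def test_omega_increases_m1_m2_value_gap(m22):
    """Asymptotically, a larger goal weight widens Q(M1) - Q(M2)."""
    gaps = []
    for omega in (0.0, 0.25, 0.5, 0.75, 1.0):
        params = {"alpha_c": 0.2, "alpha_u": 0.2, "beta_learn": 6.0,
                  "beta_test": 6.0, "omega_learn": omega}
        # long horizon: several passes over the learning schedule
        state = AgentState()
        final = None
        for rep in range(5):
            recs = simulate_agent("intrinsic", params, m22, seed=1000 + rep)
            for rec in recs:
                if rec.trial.phase != "learning":
                    continue
                _, state = agents.model_step("intrinsic", state, rec, params, m22)
            final = state
        gaps.append(final.Q.get("M1", 0.0) - final.Q.get("M2", 0.0))
    assert all(b > a for a, b in zip(gaps, gaps[1:]))
    assert gaps[0] == pytest.approx(0.0, abs=0.05)
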