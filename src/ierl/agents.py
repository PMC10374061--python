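"""Candidate learning models for context-sensitive valuation.

Five model families share one architecture: option values are learned by
a delta rule and choices follow a softmax policy.  They differ only in
the teaching signal driving the value update:

``unbiased``
    plain Q-learning on the (rescaled) objective outcome *r*.
``wsls``
    win-stay/lose-shift: the unbiased learner with learning rate fixed
    at 1 (and counterfactual updating whenever outcomes are revealed).
``range`` / ``range_z``
    range adaptation: outcomes are normalized by the context's known
    outcome range, ``rr = ((r - r_min) / (r_max - r_min)) ** z``; the
    ``range`` model fixes the nonlinearity exponent z at 1.
``intrinsic``
    intrinsically enhanced reward: a binary goal-achievement signal
    ``ir`` (1 iff the option's outcome was the best attainable on that
    trial) is mixed with the objective outcome,
    ``ier = omega * ir + (1 - omega) * r``.
``hybrid_ac``
    a Q-learner combined with an actor-critic module: a critic tracks
    each context's value V, its prediction error updates the chosen
    option's actor weight W, and the policy is a softmax over
    ``H = (1 - h) * W + h * Q``.

All functions here operate per trial on raw (unrescaled) records;
outcomes and context ranges are divided by the design's rescale factor
internally, so a single data path serves every design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import TaskDesign, TrialRecord

__all__ = [
    "MODELS",
    "AgentState",
    "param_names",
    "link_function",
    "softmax_policy",
    "delta_update",
    "range_adapted_reward",
    "intrinsic_reward",
    "intrinsically_enhanced_reward",
    "hybrid_outcome_transform",
    "choice_probabilities",
    "model_step",
]

MODELS = ("unbiased", "wsls", "range", "range_z", "intrinsic", "hybrid_ac")

#: parameters mapped to (0, inf) via exp during fitting; all others use a
#: sigmoid onto (0, 1).
_EXP_PARAMS = frozenset({"beta", "beta_learn", "beta_test", "z"})


def link_function(name: str) -> str:
    """Link used to map an unconstrained fitting variable to this parameter."""
    return "exp" if name in _EXP_PARAMS else "sigmoid"


def param_names(model_id: str, design: TaskDesign) -> tuple[str, ...]:
    """Free parameters of a model under a given design.

    Designs with loss-avoidance contexts give the range and intrinsic
    models separate gain/loss learning rates; counterfactual feedback
    adds the unchosen-option rate ``alpha_u``; test-phase feedback (B21
    variants) adds ``omega_test`` to the intrinsic model.  The hybrid
    actor-critic uses a single ``beta`` across phases.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; supported: {', '.join(MODELS)}")
    cf = ["alpha_u"] if design.has_counterfactual else []
    betas = ["beta_learn", "beta_test"]
    if model_id == "wsls":
        return tuple(betas)
    if model_id == "unbiased":
        return tuple(["alpha_c", *cf, *betas])
    if model_id in ("range", "range_z"):
        alphas = ["alpha_gains", "alpha_loss"] if design.has_losses else ["alpha_c"]
        z = ["z"] if model_id == "range_z" else []
        return tuple([*alphas, *cf, *betas, *z])
    if model_id == "intrinsic":
        alphas = ["alpha_gains", "alpha_loss"] if design.has_losses else ["alpha_c"]
        omegas = ["omega_learn"] + (["omega_test"] if design.has_test_feedback else [])
        return tuple([*alphas, *cf, *betas, *omegas])
    # hybrid_ac
    d = ["d"] if design.has_losses else []
    return tuple(["alpha_c", *cf, "alpha_critic", "alpha_actor", "h", "beta", *d])


@dataclass
class AgentState:
    """Mutable learner state.

    Q-values are keyed by option id (each option belongs to exactly one
    learning context, so (context, option) collapses to the option); the
    hybrid model additionally tracks a critic value V per context and
    actor weights W per option.  Everything starts at 0.
    """

    Q: dict[str, float] = field(default_factory=dict)
    V: dict[str, float] = field(default_factory=dict)
    W: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "AgentState":
        return AgentState(dict(self.Q), dict(self.V), dict(self.W))


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def softmax_policy(values, beta: float) -> np.ndarray:
    """Softmax choice probabilities, computed with a max shift."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("softmax requires at least one value")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    x = beta * values
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def delta_update(q: float, outcome: float, alpha: float) -> float:
    """One delta-rule step: q + alpha * (outcome - q)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("learning rate must lie in [0, 1]")
    return q + alpha * (outcome - q)


def range_adapted_reward(r: float, r_min: float, r_max: float, z: float = 1.0) -> float:
    """Range-normalized outcome, optionally warped by exponent ``z``.

    The outcome is clipped into [r_min, r_max] before normalizing, so
    the result always lies in [0, 1] with rr(r_min) = 0 and rr(r_max) = 1.
    """
    if r_max <= r_min:
        raise ValueError("degenerate context: r_max must exceed r_min")
    if z <= 0:
        raise ValueError("z must be positive")
    rr = (min(max(r, r_min), r_max) - r_min) / (r_max - r_min)
    return rr**z


def intrinsic_reward(outcome: float, other_revealed, context_r_max: float) -> int:
    """Binary goal-achievement signal for one option's outcome.

    When counterfactual outcomes are revealed, the goal is to have
    obtained the best outcome among those shown on the trial (ties count
    as achieved for every tied option).  Under partial feedback no
    comparison outcome exists, so the signal is 1 iff the outcome equals
    the context's known maximum attainable value.
    """
    others = list(other_revealed)
    if others:
        return int(outcome >= max(others))
    return int(outcome == context_r_max)


def intrinsically_enhanced_reward(r: float, ir: float, omega: float) -> float:
    """Convex mixture of intrinsic and extrinsic reward."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    return omega * ir + (1.0 - omega) * r


def hybrid_outcome_transform(r: float, d: float, has_losses: bool) -> float:
    """Loss-weighting map for the actor-critic teaching signal.

    In designs with losses, positive outcomes map to 1 - d, zero stays
    0, and negative outcomes map to -d (d = 0 neglects losses entirely,
    d = 1 neglects gains).  Without losses the outcome passes through.
    """
    if not has_losses:
        return r
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    if r > 0:
        return 1.0 - d
    if r < 0:
        return -d
    return 0.0


# ---------------------------------------------------------------------------
# One-trial interface
# ---------------------------------------------------------------------------


def _require(params: dict, name: str, model_id: str) -> float:
    try:
        return params[name]
    except KeyError:
        raise KeyError(f"model {model_id!r} requires parameter {name!r}") from None


def _chosen_rate(model_id, params, design, option_id):
    if model_id == "wsls":
        return 1.0
    if model_id in ("range", "range_z", "intrinsic") and design.has_losses:
        valence = design.home_context(option_id).valence
        name = "alpha_gains" if valence == "gain" else "alpha_loss"
        return _require(params, name, model_id)
    return _require(params, "alpha_c", model_id)


def choice_probabilities(
    model_id: str, state: AgentState, trial, params: dict[str, float]
) -> np.ndarray:
    """Softmax policy over ``trial.options`` given the current state,
    using the phase-appropriate inverse temperature."""
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; supported: {', '.join(MODELS)}")
    learning_phase = trial.phase == "learning"
    if model_id == "hybrid_ac":
        h = _require(params, "h", model_id)
        values = [
            (1.0 - h) * state.W.get(o, 0.0) + h * state.Q.get(o, 0.0)
            for o in trial.options
        ]
        beta = _require(params, "beta", model_id)
    else:
        values = [state.Q.get(o, 0.0) for o in trial.options]
        beta = _require(
            params, "beta_learn" if learning_phase else "beta_test", model_id
        )
    return softmax_policy(values, beta)


def model_step(
    model_id: str,
    state: AgentState,
    record: TrialRecord,
    params: dict[str, float],
    design: TaskDesign,
) -> tuple[np.ndarray, AgentState]:
    """Compute choice probabilities for one trial, then apply the update.

    Returns the policy's probabilities over ``record.trial.options`` (in
    order) evaluated *before* learning from the trial's feedback, and a
    new state incorporating the update.  Trials without revealed
    outcomes leave the state untouched; rating trials are not modeled.
    """
    trial = record.trial
    learning_phase = trial.phase == "learning"
    probs = choice_probabilities(model_id, state, trial, params)

    revealed = [o for o in trial.options if record.revealed.get(o, False)]
    if not revealed:
        return probs, state.copy()

    new = state.copy()
    f = design.rescale_factor
    outs = {o: record.outcomes[o] / f for o in revealed}
    ctx = design.context(trial.context_id)
    r_min, r_max = ctx.r_min / f, ctx.r_max / f

    if model_id == "hybrid_ac":
        _hybrid_update(new, record, params, design, ctx, outs)
        return probs, new

    for o in revealed:
        r = outs[o]
        if model_id in ("unbiased", "wsls"):
            target = r
        elif model_id in ("range", "range_z"):
            z = params.get("z", 1.0) if model_id == "range_z" else 1.0
            target = range_adapted_reward(r, r_min, r_max, z)
        else:  # intrinsic
            others = [outs[u] for u in revealed if u != o]
            ir = intrinsic_reward(r, others, r_max)
            if learning_phase or "omega_test" not in params:
                omega = _require(params, "omega_learn", model_id)
            else:
                omega = params["omega_test"]
            target = intrinsically_enhanced_reward(r, ir, omega)
        if o == record.choice:
            lr = _chosen_rate(model_id, params, design, o)
        else:
            lr = 1.0 if model_id == "wsls" else _require(params, "alpha_u", model_id)
        new.Q[o] = delta_update(new.Q.get(o, 0.0), target, lr)
    return probs, new


def _hybrid_update(state, record, params, design, ctx, outs):
    """Critic/actor update plus the embedded Q-learner's delta steps.

    The critic's prediction error is driven by the chosen outcome
    (loss-weighted in designs with losses); it moves both the context
    value V and the chosen option's actor weight W, after which the
    context's weights are renormalized by their absolute sum (skipped
    while all weights are still zero).
    """
    has_losses = design.has_losses
    d = params.get("d", 0.0)
    alpha_c = _require(params, "alpha_c", "hybrid_ac")

    # embedded Q-learner (loss-weighted outcomes share the actor-critic's
    # teaching signal in loss designs)
    for o in outs:
        target = hybrid_outcome_transform(outs[o], d, has_losses)
        lr = alpha_c if o == record.choice else _require(params, "alpha_u", "hybrid_ac")
        state.Q[o] = delta_update(state.Q.get(o, 0.0), target, lr)

    o_c = hybrid_outcome_transform(outs[record.choice], d, has_losses)
    cid = ctx.context_id
    delta_v = o_c - state.V.get(cid, 0.0)
    state.V[cid] = state.V.get(cid, 0.0) + _require(params, "alpha_critic", "hybrid_ac") * delta_v
    state.W[record.choice] = (
        state.W.get(record.choice, 0.0)
        + _require(params, "alpha_actor", "hybrid_ac") * delta_v
    )
    total = sum(abs(state.W.get(o, 0.0)) for o in ctx.option_ids)
    if total > 0:
        for o in ctx.option_ids:
            state.W[o] = state.W.get(o, 0.0) / total
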