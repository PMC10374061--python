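"""Compiled choice likelihoods.

Fitting evaluates the negative log likelihood of a subject's choice
sequence thousands of times, so the per-trial replay loop is compiled
with numba.  Records are first packed into flat arrays
(:func:`compile_records`); the kernel then replays the delta-rule /
actor-critic updates trial by trial for any of the model families.

The kernel mirrors :func:`ierl.agents.model_step` exactly — the pure
Python implementation drives simulation and serves as the reference
oracle for this module in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import agents
from .designs import TaskDesign, TrialRecord

__all__ = [
    "MODEL_CODES",
    "SLOT_NAMES",
    "CompiledDataset",
    "compile_records",
    "slot_vector",
    "negative_log_likelihood",
    "trial_log_likelihoods",
]

MODEL_CODES = {m: i for i, m in enumerate(agents.MODELS)}

#: fixed parameter-slot layout handed to the kernel; wrappers map each
#: model's named free parameters onto these slots.
SLOT_NAMES = (
    "alpha_c_gain",  # 0
    "alpha_c_loss",  # 1
    "alpha_u",       # 2
    "beta_learn",    # 3
    "beta_test",     # 4
    "omega_learn",   # 5
    "omega_test",    # 6
    "z",             # 7
    "alpha_critic",  # 8
    "alpha_actor",   # 9
    "h",             # 10
    "d",             # 11
)


@dataclass
class CompiledDataset:
    """A subject's choice trials packed into kernel-ready arrays."""

    n_opts: np.ndarray       # (T,) options available per trial
    opt_idx: np.ndarray      # (T, 3) global option index, -1 padded
    choice_pos: np.ndarray   # (T,) position of the chosen option
    outcomes: np.ndarray     # (T, 3) rescaled outcomes
    revealed: np.ndarray     # (T, 3) 0/1
    is_learning: np.ndarray  # (T,) 1 learning, 0 test
    r_min: np.ndarray        # (T,) rescaled context range
    r_max: np.ndarray
    ctx_idx: np.ndarray      # (T,) context index (critic V)
    ctx_opts: np.ndarray     # (T, 3) option indices of the trial's context
    opt_valence: np.ndarray  # (n_options,) 1 for loss-avoidance home context
    has_losses: bool
    n_options: int
    n_contexts: int

    @property
    def n_trials(self) -> int:
        return len(self.n_opts)


def compile_records(records: list[TrialRecord], design: TaskDesign) -> CompiledDataset:
    """Pack a subject's records (rating trials excluded) for the kernel."""
    opt_of = {o: i for i, o in enumerate(design.option_ids)}
    ctx_of = {c.context_id: i for i, c in enumerate(design.all_contexts)}
    f = design.rescale_factor

    rows = [r for r in records if r.trial.phase != "rating"]
    T = len(rows)
    n_opts = np.zeros(T, dtype=np.int64)
    opt_idx = np.full((T, 3), -1, dtype=np.int64)
    choice_pos = np.zeros(T, dtype=np.int64)
    outcomes = np.zeros((T, 3), dtype=np.float64)
    revealed = np.zeros((T, 3), dtype=np.int64)
    is_learning = np.zeros(T, dtype=np.int64)
    r_min = np.zeros(T, dtype=np.float64)
    r_max = np.ones(T, dtype=np.float64)
    ctx_idx = np.zeros(T, dtype=np.int64)
    ctx_opts = np.full((T, 3), -1, dtype=np.int64)

    for t, rec in enumerate(rows):
        trial = rec.trial
        k = len(trial.options)
        n_opts[t] = k
        for i, o in enumerate(trial.options):
            if o not in opt_of:
                raise KeyError(f"record references unknown option {o!r}")
            opt_idx[t, i] = opt_of[o]
            outcomes[t, i] = rec.outcomes.get(o, 0.0) / f
            revealed[t, i] = int(rec.revealed.get(o, False))
        choice_pos[t] = trial.options.index(rec.choice)
        is_learning[t] = int(trial.phase == "learning")
        ctx = design.context(trial.context_id)
        if ctx.r_max > ctx.r_min:
            r_min[t] = ctx.r_min / f
            r_max[t] = ctx.r_max / f
        ctx_idx[t] = ctx_of[trial.context_id]
        for i, o in enumerate(ctx.option_ids):
            ctx_opts[t, i] = opt_of[o]

    opt_valence = np.zeros(len(opt_of), dtype=np.int64)
    for o, i in opt_of.items():
        opt_valence[i] = int(design.home_context(o).valence == "loss")

    return CompiledDataset(
        n_opts, opt_idx, choice_pos, outcomes, revealed, is_learning,
        r_min, r_max, ctx_idx, ctx_opts, opt_valence,
        has_losses=design.has_losses,
        n_options=len(opt_of),
        n_contexts=len(ctx_of),
    )


def slot_vector(model_id: str, design: TaskDesign, params: dict[str, float]) -> np.ndarray:
    """Map a model's named parameters onto the kernel's 12-slot layout."""
    for name in agents.param_names(model_id, design):
        if name not in params:
            raise KeyError(f"model {model_id!r} missing parameter {name!r}")
    s = np.zeros(len(SLOT_NAMES))
    a = params.get("alpha_c", 0.0)
    s[0] = params.get("alpha_gains", a)
    s[1] = params.get("alpha_loss", a)
    s[2] = params.get("alpha_u", 0.0)
    beta = params.get("beta", 0.0)
    s[3] = params.get("beta_learn", beta)
    s[4] = params.get("beta_test", beta)
    s[5] = params.get("omega_learn", 0.0)
    s[6] = params.get("omega_test", s[5])
    s[7] = params.get("z", 1.0)
    s[8] = params.get("alpha_critic", 0.0)
    s[9] = params.get("alpha_actor", 0.0)
    s[10] = params.get("h", 0.0)
    s[11] = params.get("d", 0.0)
    return s


@njit(cache=True)
def _nll_kernel(
    model, slots, n_opts, opt_idx, choice_pos, outcomes, revealed,
    is_learning, r_min, r_max, ctx_idx, ctx_opts, opt_valence,
    has_losses, n_options, n_contexts, trial_ll,
):  # pragma: no cover - exercised through the wrappers
    Q = np.zeros(n_options)
    W = np.zeros(n_options)
    V = np.zeros(n_contexts)
    h = slots[10]
    d = slots[11]
    nll = 0.0
    T = len(n_opts)
    vals = np.zeros(3)
    for t in range(T):
        k = n_opts[t]
        for i in range(k):
            oi = opt_idx[t, i]
            if model == 5:
                vals[i] = (1.0 - h) * W[oi] + h * Q[oi]
            else:
                vals[i] = Q[oi]
        if model == 5:
            beta = slots[3]
        elif is_learning[t] == 1:
            beta = slots[3]
        else:
            beta = slots[4]
        m = -1.0e300
        for i in range(k):
            if beta * vals[i] > m:
                m = beta * vals[i]
        se = 0.0
        for i in range(k):
            se += np.exp(beta * vals[i] - m)
        logp = beta * vals[choice_pos[t]] - m - np.log(se)
        trial_ll[t] = logp
        nll -= logp

        nrev = 0
        maxrev = -1.0e300
        for i in range(k):
            if revealed[t, i] == 1:
                nrev += 1
                if outcomes[t, i] > maxrev:
                    maxrev = outcomes[t, i]
        if nrev == 0:
            continue

        for i in range(k):
            if revealed[t, i] == 0:
                continue
            oi = opt_idx[t, i]
            r = outcomes[t, i]
            if model <= 1:  # unbiased / wsls
                tgt = r
            elif model <= 3:  # range / range_z
                z = slots[7] if model == 3 else 1.0
                rc = r
                if rc < r_min[t]:
                    rc = r_min[t]
                if rc > r_max[t]:
                    rc = r_max[t]
                tgt = ((rc - r_min[t]) / (r_max[t] - r_min[t])) ** z
            elif model == 4:  # intrinsic
                if nrev >= 2:
                    ir = 1.0 if r >= maxrev else 0.0
                else:
                    ir = 1.0 if r == r_max[t] else 0.0
                om = slots[5] if is_learning[t] == 1 else slots[6]
                tgt = om * ir + (1.0 - om) * r
            else:  # hybrid embedded Q-learner
                if has_losses:
                    if r > 0.0:
                        tgt = 1.0 - d
                    elif r < 0.0:
                        tgt = -d
                    else:
                        tgt = 0.0
                else:
                    tgt = r
            if i == choice_pos[t]:
                if model == 1:
                    lr = 1.0
                elif has_losses and (model == 2 or model == 3 or model == 4):
                    lr = slots[1] if opt_valence[oi] == 1 else slots[0]
                else:
                    lr = slots[0]
            else:
                lr = 1.0 if model == 1 else slots[2]
            Q[oi] += lr * (tgt - Q[oi])

        if model == 5:
            rc = outcomes[t, choice_pos[t]]
            if has_losses:
                if rc > 0.0:
                    oc = 1.0 - d
                elif rc < 0.0:
                    oc = -d
                else:
                    oc = 0.0
            else:
                oc = rc
            ci = ctx_idx[t]
            dv = oc - V[ci]
            V[ci] += slots[8] * dv
            W[opt_idx[t, choice_pos[t]]] += slots[9] * dv
            tot = 0.0
            for j in range(3):
                cj = ctx_opts[t, j]
                if cj >= 0:
                    tot += abs(W[cj])
            if tot > 0.0:
                for j in range(3):
                    cj = ctx_opts[t, j]
                    if cj >= 0:
                        W[cj] = W[cj] / tot
    return nll


def _run_kernel(model_id, slots, ds: CompiledDataset):
    trial_ll = np.zeros(ds.n_trials)
    nll = _nll_kernel(
        MODEL_CODES[model_id], np.asarray(slots, dtype=np.float64),
        ds.n_opts, ds.opt_idx, ds.choice_pos, ds.outcomes, ds.revealed,
        ds.is_learning, ds.r_min, ds.r_max, ds.ctx_idx, ds.ctx_opts,
        ds.opt_valence, ds.has_losses, ds.n_options, ds.n_contexts, trial_ll,
    )
    return nll, trial_ll


def negative_log_likelihood(
    model_id: str,
    params: dict[str, float],
    records: list[TrialRecord],
    design: TaskDesign,
    dataset: CompiledDataset | None = None,
) -> float:
    """-sum(log P(choice_t)) over the learning and test trials.

    ``dataset`` may be passed to reuse a compiled record set across many
    evaluations (the fitting loop does this).
    """
    ds = dataset if dataset is not None else compile_records(records, design)
    slots = slot_vector(model_id, design, params)
    nll, _ = _run_kernel(model_id, slots, ds)
    return float(nll)


def trial_log_likelihoods(
    model_id: str,
    params: dict[str, float],
    records: list[TrialRecord],
    design: TaskDesign,
) -> np.ndarray:
    """Per-trial log choice probabilities (rating trials excluded)."""
    ds = compile_records(records, design)
    slots = slot_vector(model_id, design, params)
    _, trial_ll = _run_kernel(model_id, slots, ds)
    return trial_ll
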