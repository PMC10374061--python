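"""Agent-environment simulation loops.

Three entry points cover the package's simulation needs:

* :func:`simulate_agent` runs one agent through a design's learning,
  test and (where present) rating schedules, or replays a fixed trial /
  outcome sequence;
* :func:`simulate_ex_ante` draws cohorts of agents from the ex ante
  parameter priors (beta ~ Gamma(1.2, 0.2) in shape/rate form, learning
  rates ~ Beta(1.1, 1.1), z ~ Gamma(3, 3), omega ~ Beta(2, 2)) and
  summarizes test-phase choice rates per stimulus;
* :func:`posterior_predictive` replays each fitted subject's observed
  stimulus and outcome sequence with model-sampled choices.

Seeding is hierarchical (master seed -> per-subject streams -> schedule
/ outcome / choice streams), so cohorts are bit-reproducible and adding
subjects never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents
from .designs import (
    TaskDesign,
    Trial,
    TrialRecord,
    generate_learning_schedule,
    generate_rating_schedule,
    generate_test_schedule,
    sample_outcomes,
)

__all__ = [
    "PriorSpec",
    "ex_ante_prior",
    "SimulatedCohort",
    "simulate_agent",
    "simulate_cohort",
    "simulate_ex_ante",
    "posterior_predictive",
    "test_choice_rates",
]


@dataclass(frozen=True)
class PriorSpec:
    """Sampling distributions for generating agent parameters.

    ``distributions`` maps a parameter-name prefix to a
    ``(family, *hyperparameters)`` tuple, family in {'beta', 'gamma'}
    with gamma parametrized by (shape, rate).  Lookup strips trailing
    phase suffixes, so 'beta_learn' and 'beta_test' share the 'beta'
    entry.
    """

    distributions: dict[str, tuple] = field(default_factory=dict)

    def _entry(self, name: str):
        if name in self.distributions:
            return self.distributions[name]
        root = name.split("_")[0]
        if root in self.distributions:
            return self.distributions[root]
        if name.startswith("alpha") and "alpha" in self.distributions:
            return self.distributions["alpha"]
        raise KeyError(f"prior has no distribution for parameter {name!r}")

    def draw(self, names, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name in names:
            family, *hyper = self._entry(name)
            if family == "beta":
                out[name] = float(rng.beta(*hyper))
            elif family == "gamma":
                shape, rate = hyper
                out[name] = float(rng.gamma(shape, 1.0 / rate))
            else:
                raise ValueError(f"unknown prior family {family!r}")
        return out


def ex_ante_prior() -> PriorSpec:
    """The ex ante simulation priors used for prospective predictions."""
    return PriorSpec(
        {
            "beta": ("gamma", 1.2, 0.2),
            "alpha": ("beta", 1.1, 1.1),
            "z": ("gamma", 3.0, 3.0),
            "omega": ("beta", 2.0, 2.0),
            "h": ("beta", 1.1, 1.1),
            "d": ("beta", 1.1, 1.1),
        }
    )


@dataclass
class SimulatedCohort:
    """A set of simulated subjects with their generating parameters."""

    design_id: str
    variant: str
    model_id: str
    params: list[dict[str, float]]
    records: list[list[TrialRecord]]
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.records)


def _revealed_mask(trial: Trial, choice: str) -> dict[str, bool]:
    if trial.phase == "rating" or trial.feedback == "none":
        return {o: False for o in trial.options}
    if trial.feedback == "complete":
        return {o: True for o in trial.options}
    return {o: o == choice for o in trial.options}


def simulate_agent(
    model_id: str,
    params: dict[str, float],
    design: TaskDesign,
    seed,
    trials: list[Trial] | None = None,
    outcome_plan: list[dict[str, float]] | None = None,
) -> list[TrialRecord]:
    """Simulate one agent through the task.

    By default the learning, test and rating schedules are generated
    from the seed and outcomes are sampled fresh.  Passing ``trials``
    (and optionally ``outcome_plan``, one outcome map per trial) replays
    a fixed stimulus sequence instead — the posterior-predictive path.

    Rating trials store the agent's current value estimate, mapped back
    to the design's raw outcome scale, as the trial's "outcome".
    """
    names = agents.param_names(model_id, design)
    missing = [n for n in names if n not in params]
    if missing:
        raise KeyError(f"model {model_id!r} missing parameter(s): {', '.join(missing)}")

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    sched_rng, outcome_rng, choice_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    if trials is None:
        trials = (
            generate_learning_schedule(design, sched_rng)
            + generate_test_schedule(design, sched_rng)
            + generate_rating_schedule(design, sched_rng)
        )

    state = agents.AgentState()
    records: list[TrialRecord] = []
    for t, trial in enumerate(trials):
        if trial.phase == "rating":
            oid = trial.options[0]
            rating = state.Q.get(oid, 0.0) * design.rescale_factor
            records.append(
                TrialRecord(trial, oid, {oid: rating}, {oid: False})
            )
            continue
        if outcome_plan is not None:
            outcomes = dict(outcome_plan[t])
        else:
            outcomes = sample_outcomes(trial, design, outcome_rng)
        probs = agents.choice_probabilities(model_id, state, trial, params)
        choice = trial.options[choice_rng.choice(len(trial.options), p=probs)]
        record = TrialRecord(trial, choice, outcomes, _revealed_mask(trial, choice))
        _, state = agents.model_step(model_id, state, record, params, design)
        records.append(record)
    return records


def simulate_cohort(
    model_id: str,
    params_per_subject: list[dict[str, float]],
    design: TaskDesign,
    seed,
) -> SimulatedCohort:
    """Simulate one agent per parameter set under a hierarchical seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(params_per_subject))
    records = [
        simulate_agent(model_id, p, design, child)
        for p, child in zip(params_per_subject, children)
    ]
    return SimulatedCohort(
        design.design_id, design.variant, model_id, list(params_per_subject), records,
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_ex_ante(
    model_id: str,
    design: TaskDesign,
    n_agents: int = 100,
    prior: PriorSpec | None = None,
    seed=0,
) -> tuple[SimulatedCohort, pd.DataFrame]:
    """Prospective simulation: draw parameters from the ex ante priors,
    simulate each agent once, and summarize test-phase choice rates.

    Returns the cohort and a DataFrame with one row per stimulus
    (columns ``option_id``, ``choice_rate``, ``sem``), the standard
    prospective-prediction summary.
    """
    prior = prior or ex_ante_prior()
    names = agents.param_names(model_id, design)
    ss = np.random.SeedSequence(seed)
    prior_ss, cohort_ss = ss.spawn(2)
    rng = np.random.default_rng(prior_ss)
    params = [prior.draw(names, rng) for _ in range(n_agents)]
    cohort = simulate_cohort(model_id, params, design, cohort_ss)
    return cohort, test_choice_rates(cohort)


def test_choice_rates(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-stimulus test-phase choice rates: for each subject, the
    fraction of test presentations of a stimulus in which it was chosen,
    then mean and SEM across subjects."""
    per_subject = []
    for recs in cohort.records:
        seen: dict[str, int] = {}
        chosen: dict[str, int] = {}
        for r in recs:
            if r.trial.phase != "test":
                continue
            for o in r.trial.options:
                seen[o] = seen.get(o, 0) + 1
            chosen[r.choice] = chosen.get(r.choice, 0) + 1
        per_subject.append(
            {o: chosen.get(o, 0) / n for o, n in seen.items() if n > 0}
        )
    if not per_subject:
        return pd.DataFrame(columns=["option_id", "choice_rate", "sem"])
    df = pd.DataFrame(per_subject)
    n = df.shape[0]
    out = pd.DataFrame(
        {
            "option_id": df.columns,
            "choice_rate": df.mean(axis=0).to_numpy(),
            "sem": df.std(axis=0, ddof=1).to_numpy() / np.sqrt(n) if n > 1 else np.nan,
        }
    )
    return out.reset_index(drop=True)


def posterior_predictive(
    model_id: str,
    fitted_params: list[dict[str, float]],
    observed: list[list[TrialRecord]],
    design: TaskDesign,
    n_reps: int = 10,
    seed=0,
) -> tuple[SimulatedCohort, pd.DataFrame]:
    """Replay each subject's observed trial sequence with model-sampled
    choices, ``n_reps`` times per subject.

    The full per-option outcome maps stored in the observed records are
    replayed, so simulated agents always see well-defined outcomes even
    when their choice differs from the subject's.  Returns the combined
    cohort (subject-major, replicate-minor ordering) and a per-context
    correct-choice-rate summary averaged over replicates.
    """
    if len(fitted_params) != len(observed):
        raise ValueError(
            f"{len(fitted_params)} parameter sets for {len(observed)} subjects"
        )
    from .recovery import behavioral_summary  # local import: avoid cycle

    ss = np.random.SeedSequence(seed)
    all_params, all_records = [], []
    for params, recs, subj_ss in zip(fitted_params, observed, ss.spawn(len(observed))):
        trials = [r.trial for r in recs]
        plan = [dict(r.outcomes) for r in recs]
        for rep_ss in subj_ss.spawn(n_reps):
            all_params.append(dict(params))
            all_records.append(
                simulate_agent(
                    model_id, params, design, rep_ss, trials=trials, outcome_plan=plan
                )
            )
    cohort = SimulatedCohort(
        design.design_id, design.variant, model_id, all_params, all_records
    )
    summaries = [behavioral_summary(recs, design) for recs in all_records]
    rows = []
    for phase in ("learning", "test"):
        key = f"correct_rate_{phase}"
        ctxs: dict[str, list[float]] = {}
        for s in summaries:
            for ctx, rate in s[key].items():
                ctxs.setdefault(ctx, []).append(rate)
        for ctx, rates in ctxs.items():
            rows.append(
                {
                    "phase": phase,
                    "context_id": ctx,
                    "correct_rate": float(np.mean(rates)),
                    "sem": float(np.std(rates, ddof=1) / np.sqrt(len(rates)))
                    if len(rates) > 1
                    else np.nan,
                }
            )
    return cohort, pd.DataFrame(rows)
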