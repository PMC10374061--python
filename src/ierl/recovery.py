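"""Model recovery, parameter recovery and behavioral summaries.

These are the validation instruments of the modelling pipeline:
simulate-and-refit confusion matrices check that the candidate models
are identifiable on a design; parameter recovery checks that the
mixture weight omega (and friends) can be retrieved from data of the
size actually collected; behavioral summaries compute the per-context
correct-choice rates and the design-specific signatures of
context-sensitive valuation (e.g. the below-chance choice rate in B21's
recombined context 8, or the M1 - M2 choice-rate difference in M22).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import agents
from .designs import TaskDesign, TrialRecord
from .inference import fit_hbi, fit_map_laplace
from .simulate import PriorSpec, ex_ante_prior, simulate_cohort

__all__ = [
    "ConfusionMatrix",
    "model_recovery",
    "parameter_recovery",
    "behavioral_summary",
    "signature_scalar",
    "omega_signature_correlation",
]


@dataclass
class ConfusionMatrix:
    """Simulate-and-refit outcome: generating models in rows."""

    model_ids: tuple[str, ...]
    frequencies: pd.DataFrame  # HBI model frequencies per generating model
    pxp: pd.DataFrame          # protected exceedance probabilities
    n_subjects: int
    seed: int | None = None

    @property
    def diagonal(self) -> np.ndarray:
        return np.array(
            [self.frequencies.loc[m, m] for m in self.model_ids]
        )

    @property
    def recovered(self) -> bool:
        """True when every generating model wins its own row."""
        return all(
            self.frequencies.loc[m].idxmax() == m for m in self.model_ids
        )


def model_recovery(
    design: TaskDesign,
    model_ids=("intrinsic", "range_z", "wsls"),
    n_subjects: int = 50,
    prior: PriorSpec | None = None,
    seed=0,
    generating_params=None,
    **hbi_kwargs,
) -> ConfusionMatrix:
    """Confusion matrix over candidate models by simulate-and-refit.

    For each generating model, a cohort of ``n_subjects`` agents is
    simulated (parameters drawn from the ex ante priors unless
    ``generating_params`` supplies model_id -> list-of-dicts), the full
    candidate set is fit hierarchically, and the resulting model
    frequencies and protected exceedance probabilities are recorded.
    Diagonal dominance of the frequency grid is the recovery criterion.
    """
    model_ids = tuple(model_ids)
    prior = prior or ex_ante_prior()
    ss = np.random.SeedSequence(seed)
    freq_rows, pxp_rows = [], []
    for gen_model, gen_ss in zip(model_ids, ss.spawn(len(model_ids))):
        par_ss, sim_ss, fit_ss = gen_ss.spawn(3)
        if generating_params is not None and gen_model in generating_params:
            params = list(generating_params[gen_model])
        else:
            rng = np.random.default_rng(par_ss)
            names = agents.param_names(gen_model, design)
            params = [prior.draw(names, rng) for _ in range(n_subjects)]
        cohort = simulate_cohort(gen_model, params, design, sim_ss)
        if len(model_ids) == 1:
            # degenerate single-candidate "matrix"
            freq_rows.append(np.array([1.0]))
            pxp_rows.append(np.array([1.0]))
            continue
        group = fit_hbi(
            model_ids, cohort.records, design,
            seed=fit_ss.generate_state(1)[0] % (2**31), **hbi_kwargs,
        )
        freq_rows.append(group.frequencies)
        pxp_rows.append(group.pxp)
    idx = pd.Index(model_ids, name="generating")
    cols = pd.Index(model_ids, name="fitted")
    return ConfusionMatrix(
        model_ids=model_ids,
        frequencies=pd.DataFrame(freq_rows, index=idx, columns=cols),
        pxp=pd.DataFrame(pxp_rows, index=idx, columns=cols),
        n_subjects=len(params),
        seed=seed if isinstance(seed, int) else None,
    )


def parameter_recovery(
    model_id: str,
    design: TaskDesign,
    n_subjects: int = 100,
    prior: PriorSpec | None = None,
    seed=0,
    n_restarts: int = 5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate agents from prior draws, refit each, and rank-correlate.

    Returns a DataFrame with ``<name>_true`` / ``<name>_fit`` columns
    (one row per subject) and a dict of per-parameter Spearman
    correlations between generating and recovered values.
    """
    if n_subjects < 10:
        raise ValueError("parameter recovery needs >= 10 subjects")
    prior = prior or ex_ante_prior()
    names = agents.param_names(model_id, design)
    ss = np.random.SeedSequence(seed)
    par_ss, sim_ss, fit_ss = ss.spawn(3)
    rng = np.random.default_rng(par_ss)
    params = [prior.draw(names, rng) for _ in range(n_subjects)]
    cohort = simulate_cohort(model_id, params, design, sim_ss)
    fit_seeds = [s.generate_state(1)[0] % (2**31) for s in fit_ss.spawn(n_subjects)]
    rows = []
    for true_p, recs, s in zip(params, cohort.records, fit_seeds):
        fit = fit_map_laplace(model_id, recs, design, n_restarts=n_restarts, seed=s)
        row = {f"{n}_true": true_p[n] for n in names}
        row.update({f"{n}_fit": fit.params[n] for n in names})
        sig = signature_scalar(behavioral_summary(recs, design), design)
        if sig is not None:
            row["signature"] = sig
        rows.append(row)
    df = pd.DataFrame(rows)
    rho = {}
    for n in names:
        res = stats.spearmanr(df[f"{n}_true"], df[f"{n}_fit"])
        rho[n] = float(res.statistic)
    return df, rho


# ---------------------------------------------------------------------------
# Behavioral summaries
# ---------------------------------------------------------------------------


def _correct_option(trial, design: TaskDesign) -> str:
    evs = [design.expected_value(o) for o in trial.options]
    return trial.options[int(np.argmax(evs))]


def _pair_rate(records, design, option_a, option_b):
    """Fraction of test trials presenting exactly {a, b} where a was
    chosen; None if the pairing never occurred."""
    shown = chosen = 0
    target = frozenset((option_a, option_b))
    for r in records:
        if r.trial.phase == "test" and frozenset(r.trial.options) == target:
            shown += 1
            chosen += int(r.choice == option_a)
    return chosen / shown if shown else None


def behavioral_summary(records: list[TrialRecord], design: TaskDesign) -> dict:
    """Per-context correct-choice rates, per-stimulus test choice rates,
    and the design's context-sensitivity signature scalars.

    'Correct' means the available option with the highest design
    expected value.  Phases with no trials yield absent entries rather
    than zeros.
    """
    out: dict = {"correct_rate_learning": {}, "correct_rate_test": {},
                 "test_choice_rate": {}, "signatures": {}}
    counts = {"learning": {}, "test": {}}
    seen: dict[str, int] = {}
    chosen: dict[str, int] = {}
    for r in records:
        phase = r.trial.phase
        if phase == "rating":
            continue
        n, c = counts[phase].get(r.trial.context_id, (0, 0)) or (0, 0)
        correct = int(r.choice == _correct_option(r.trial, design))
        counts[phase][r.trial.context_id] = (n + 1, c + correct)
        if phase == "test":
            for o in r.trial.options:
                seen[o] = seen.get(o, 0) + 1
            chosen[r.choice] = chosen.get(r.choice, 0) + 1
    for phase, key in (("learning", "correct_rate_learning"), ("test", "correct_rate_test")):
        for ctx, (n, c) in counts[phase].items():
            out[key][ctx] = c / n
    for o, n in seen.items():
        out["test_choice_rate"][o] = chosen.get(o, 0) / n

    sig = out["signatures"]
    did = design.design_id
    if did == "B21" and "8" in out["correct_rate_test"]:
        # choosing the EV=0.75 item over the EV=2.5 item in the
        # recombined dEV=1.75 pair
        sig["context8_error_rate"] = 1.0 - out["correct_rate_test"]["8"]
    elif did == "B18":
        # irrational preferences: optimal small-gain (EV .075, option C)
        # over suboptimal large-gain (EV .25, option B); optimal
        # small-loss (EV -.025, G) over suboptimal small-gain (EV .025, D)
        errs = [_pair_rate(records, design, "C", "B"),
                _pair_rate(records, design, "G", "D")]
        errs = [e for e in errs if e is not None]
        if errs:
            sig["cross_context_error_rate"] = float(np.mean(errs))
    elif did == "G12":
        # loss-context optimal (EV -0.1 / -0.2) chosen over gain-context
        # suboptimal (EV 0.1 / 0.2)
        errs = [_pair_rate(records, design, "E", "B"),
                _pair_rate(records, design, "G", "D")]
        errs = [e for e in errs if e is not None]
        if errs:
            sig["cross_context_error_rate"] = float(np.mean(errs))
    elif did in ("M22", "M22R", "M22B"):
        tcr = out["test_choice_rate"]
        if "M1" in tcr and "M2" in tcr:
            sig["m1_choice_rate"] = tcr["M1"]
            sig["m2_choice_rate"] = tcr["M2"]
            sig["m1_minus_m2"] = tcr["M1"] - tcr["M2"]
        head = _pair_rate(records, design, "M1", "M2")
        if head is not None:
            sig["m1_vs_m2_rate"] = head
        m1_low = [_pair_rate(records, design, "M1", low) for low in ("L1", "L2")]
        m2_low = [_pair_rate(records, design, "M2", low) for low in ("L1", "L2")]
        m1_low = [v for v in m1_low if v is not None]
        m2_low = [v for v in m2_low if v is not None]
        if m1_low and m2_low:
            sig["m_vs_low_difference"] = float(np.mean(m1_low) - np.mean(m2_low))
    return out


def signature_scalar(summary: dict, design: TaskDesign) -> float | None:
    """The single signature value used for omega correlations."""
    sig = summary["signatures"]
    if design.design_id == "B21":
        return sig.get("context8_error_rate")
    if design.design_id in ("B18", "G12"):
        return sig.get("cross_context_error_rate")
    return sig.get("m1_minus_m2")


def omega_signature_correlation(omegas, signatures) -> tuple[float, float]:
    """Spearman rank correlation between fitted (or generating) omega
    values and the behavioral signature, one pair per subject.

    Returns (rho, p); a degenerate input (constant omega or signature)
    yields (nan, nan).
    """
    omegas = np.asarray(omegas, dtype=float)
    signatures = np.asarray(signatures, dtype=float)
    if omegas.shape != signatures.shape:
        raise ValueError("omega and signature vectors differ in length")
    if np.all(omegas == omegas[0]) or np.all(signatures == signatures[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(omegas, signatures)
    return float(res.statistic), float(res.pvalue)
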