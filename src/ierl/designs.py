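"""Bandit-task designs for context-sensitive valuation experiments.

Encodes the five experimental designs used throughout the package (B21,
B18, G12, B22 and M22 with its control variant M22B / replication M22R)
as data: the option outcome distributions of every learning context, the
recombined pairings of the transfer (test) phase, the feedback regime of
each phase, and the presentation order.  Each design also carries the
outcome rescaling factor that maps raw outcomes into [-1, 1] (losses
present) or [0, 1] so that softmax temperatures are comparable across
experiments.

Designs come in two outcome families:

* Bernoulli-magnitude options (B21, B18, G12): the option yields its
  "high" outcome with probability ``p_high`` and its "low" outcome
  otherwise, with magnitudes such as {10, 0}, {1, 0}, {0, -1}.
* Gaussian options (B22, M22): outcomes are drawn from a normal with a
  fixed mean (14, 32, 50 or 86) and variance 4.

A context is the set of 2-3 options that are presented together during
learning; its ``r_min``/``r_max`` are the extreme outcome values
attainable in the context (for Gaussian options, the extreme option
means, which are treated as known to the learner).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OptionSpec",
    "ContextSpec",
    "Trial",
    "TrialRecord",
    "TaskDesign",
    "build_design",
    "available_designs",
    "generate_learning_schedule",
    "generate_test_schedule",
    "generate_rating_schedule",
    "sample_outcomes",
    "rescale_outcomes",
    "B21_VARIANTS",
]

#: the 8 variant codes of design B21: learning feedback (P)artial/(C)omplete,
#: test feedback (P)artial/(C)omplete/(N)one, presentation (I)nterleaved/(B)locked.
#: When test feedback is given it matches the learning-phase feedback type.
B21_VARIANTS = ("PPI", "PPB", "PNI", "PNB", "CCI", "CCB", "CNI", "CNB")

_FEEDBACK_CODE = {"P": "partial", "C": "complete", "N": "none"}


@dataclass(frozen=True)
class OptionSpec:
    """One bandit arm: a stochastic outcome distribution with a label."""

    option_id: str
    kind: str  # 'bernoulli' | 'gaussian'
    high: float = 0.0
    low: float = 0.0
    p_high: float = 0.0
    mean: float = 0.0
    sd: float = 2.0

    def __post_init__(self):
        if self.kind not in ("bernoulli", "gaussian"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "bernoulli" and not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must lie in [0, 1]")

    @property
    def expected_value(self) -> float:
        if self.kind == "bernoulli":
            return self.p_high * self.high + (1.0 - self.p_high) * self.low
        return self.mean

    @property
    def support_min(self) -> float:
        """Smallest 'known' outcome value (the mean, for Gaussian options)."""
        return min(self.high, self.low) if self.kind == "bernoulli" else self.mean

    @property
    def support_max(self) -> float:
        return max(self.high, self.low) if self.kind == "bernoulli" else self.mean


@dataclass(frozen=True)
class ContextSpec:
    """A set of 2-3 options presented together, with its outcome range.

    ``valence`` is 'loss' for loss-avoidance contexts (all attainable
    outcomes <= 0) and 'gain' otherwise; it selects the gain vs loss
    learning rate in models that distinguish the two.
    """

    context_id: str
    options: tuple[OptionSpec, ...]
    is_test_pairing: bool = False

    def __post_init__(self):
        if not 2 <= len(self.options) <= 3:
            raise ValueError("a context holds 2 or 3 options")
        # test pairings of equal-mean options legitimately have zero range
        # (their range is never used: no-feedback trials trigger no update)
        if not self.is_test_pairing and self.r_min >= self.r_max:
            raise ValueError(f"degenerate context {self.context_id}: r_min >= r_max")

    @property
    def r_min(self) -> float:
        return min(o.support_min for o in self.options)

    @property
    def r_max(self) -> float:
        return max(o.support_max for o in self.options)

    @property
    def valence(self) -> str:
        return "loss" if self.r_max <= 0 else "gain"

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.option_id for o in self.options)


@dataclass(frozen=True)
class Trial:
    """One presentation: which options are available, under what feedback."""

    phase: str  # 'learning' | 'test' | 'rating'
    context_id: str
    options: tuple[str, ...]
    feedback: str  # 'partial' | 'complete' | 'none'

    def __post_init__(self):
        if self.phase not in ("learning", "test", "rating"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase != "rating" and not 2 <= len(self.options) <= 3:
            raise ValueError("choice trials present 2 or 3 options")


@dataclass(frozen=True)
class TrialRecord:
    """A realized trial: the choice made and every outcome drawn.

    Outcomes are drawn for *all* available options, including options
    whose outcome was never shown (``revealed[o] is False``); the hidden
    draws serve as counterfactual ground truth for complete-feedback
    variants and for the intrinsic-reward oracle.
    """

    trial: Trial
    choice: str
    outcomes: dict[str, float]
    revealed: dict[str, bool]

    def __post_init__(self):
        if self.trial.phase != "rating" and self.choice not in self.trial.options:
            raise ValueError(f"choice {self.choice!r} not among {self.trial.options}")


@dataclass(frozen=True)
class TaskDesign:
    """Full specification of one experiment."""

    design_id: str
    variant: str
    contexts: tuple[ContextSpec, ...]
    test_contexts: tuple[ContextSpec, ...]
    learning_pairings: tuple[tuple[str, tuple[str, ...], int], ...]
    # (context_id, option_ids, n_repeats) for each learning pairing type
    test_repeats: int
    rescale_factor: float
    learn_feedback: str
    test_feedback: str
    presentation: str  # 'interleaved' | 'blocked'
    rating_repeats: int = 0
    complete_fraction: float = 1.0
    # fraction of learning trials with complete feedback when
    # learn_feedback == 'complete' (B18 experiment 2 uses 0.5)
    session_breaks: tuple[int, ...] = ()
    # learning-pairing indices at which a fresh session starts (B22)

    def __post_init__(self):
        if self.rescale_factor <= 0:
            raise ValueError("rescale_factor must be positive")

    @property
    def has_losses(self) -> bool:
        return any(c.r_min < 0 for c in self.contexts)

    @property
    def has_counterfactual(self) -> bool:
        return self.learn_feedback == "complete" or self.test_feedback == "complete"

    @property
    def has_test_feedback(self) -> bool:
        return self.test_feedback in ("partial", "complete")

    @property
    def all_contexts(self) -> tuple[ContextSpec, ...]:
        return self.contexts + self.test_contexts

    def context(self, context_id: str) -> ContextSpec:
        for c in self.all_contexts:
            if c.context_id == context_id:
                return c
        raise KeyError(f"unknown context {context_id!r}")

    def option(self, option_id: str) -> OptionSpec:
        return self._option_index()[option_id]

    def _option_index(self) -> dict[str, OptionSpec]:
        idx = {}
        for c in self.contexts:
            for o in c.options:
                idx[o.option_id] = o
        return idx

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(self._option_index())

    def home_context(self, option_id: str) -> ContextSpec:
        """Learning context an option belongs to."""
        for c in self.contexts:
            if option_id in c.option_ids:
                return c
        raise KeyError(f"unknown option {option_id!r}")

    def expected_value(self, option_id: str) -> float:
        return self.option(option_id).expected_value

    # -- serialization (user-defined designs) --------------------------------

    def to_json(self) -> str:
        def _ctx(c):
            return {
                "context_id": c.context_id,
                "options": [vars(o) for o in c.options],
                "is_test_pairing": c.is_test_pairing,
            }

        payload = {
            "schema_version": 1,
            "design_id": self.design_id,
            "variant": self.variant,
            "contexts": [_ctx(c) for c in self.contexts],
            "test_contexts": [_ctx(c) for c in self.test_contexts],
            "learning_pairings": [list(p[:2]) + [p[2]] for p in self.learning_pairings],
            "test_repeats": self.test_repeats,
            "rescale_factor": self.rescale_factor,
            "learn_feedback": self.learn_feedback,
            "test_feedback": self.test_feedback,
            "presentation": self.presentation,
            "rating_repeats": self.rating_repeats,
            "complete_fraction": self.complete_fraction,
            "session_breaks": list(self.session_breaks),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        d = json.loads(text)

        def _ctx(c):
            return ContextSpec(
                context_id=c["context_id"],
                options=tuple(OptionSpec(**o) for o in c["options"]),
                is_test_pairing=c.get("is_test_pairing", False),
            )

        return cls(
            design_id=d["design_id"],
            variant=d["variant"],
            contexts=tuple(_ctx(c) for c in d["contexts"]),
            test_contexts=tuple(_ctx(c) for c in d["test_contexts"]),
            learning_pairings=tuple(
                (p[0], tuple(p[1]), int(p[2])) for p in d["learning_pairings"]
            ),
            test_repeats=int(d["test_repeats"]),
            rescale_factor=float(d["rescale_factor"]),
            learn_feedback=d["learn_feedback"],
            test_feedback=d["test_feedback"],
            presentation=d["presentation"],
            rating_repeats=int(d.get("rating_repeats", 0)),
            complete_fraction=float(d.get("complete_fraction", 1.0)),
            session_breaks=tuple(d.get("session_breaks", ())),
        )


# ---------------------------------------------------------------------------
# Built-in designs
# ---------------------------------------------------------------------------


def _bern(option_id, high, low, p_high):
    return OptionSpec(option_id, "bernoulli", high=high, low=low, p_high=p_high)


def _gauss(option_id, mean, sd=2.0):
    return OptionSpec(option_id, "gaussian", mean=mean, sd=sd)


def _pair_context(context_id, a, b):
    """Test pairing across learning contexts; range spans both supports."""
    return ContextSpec(context_id, (a, b), is_test_pairing=True)


def _build_b21(variant: str) -> TaskDesign:
    if variant not in B21_VARIANTS:
        raise ValueError(
            f"unknown B21 variant {variant!r}; supported: {', '.join(B21_VARIANTS)}"
        )
    learn_fb = _FEEDBACK_CODE[variant[0]]
    test_fb = _FEEDBACK_CODE[variant[1]]
    presentation = "interleaved" if variant[2] == "I" else "blocked"

    # four learning contexts: big-magnitude pairs (10/0) and small (1/0),
    # favourable outcome with p = .75 for the good option, .25 for the bad.
    opts = {
        "A": _bern("A", 10, 0, 0.75),
        "B": _bern("B", 10, 0, 0.25),
        "C": _bern("C", 10, 0, 0.75),
        "D": _bern("D", 10, 0, 0.25),
        "E": _bern("E", 1, 0, 0.75),
        "F": _bern("F", 1, 0, 0.25),
        "G": _bern("G", 1, 0, 0.75),
        "H": _bern("H", 1, 0, 0.25),
    }
    contexts = (
        ContextSpec("1", (opts["A"], opts["B"])),
        ContextSpec("2", (opts["C"], opts["D"])),
        ContextSpec("3", (opts["E"], opts["F"])),
        ContextSpec("4", (opts["G"], opts["H"])),
    )
    # test recombinations pit 10-magnitude against 1-magnitude items,
    # giving dEV = 6.75, 2.25, 7.25 and 1.75 (contexts 5-8).  Context 8
    # pairs the formerly suboptimal EV=2.5 item with the formerly optimal
    # EV=0.75 item: the classic "irrational" transfer probe.
    test_contexts = (
        _pair_context("5", opts["A"], opts["E"]),  # 7.5 vs 0.75
        _pair_context("6", opts["B"], opts["F"]),  # 2.5 vs 0.25
        _pair_context("7", opts["C"], opts["H"]),  # 7.5 vs 0.25
        _pair_context("8", opts["D"], opts["G"]),  # 2.5 vs 0.75
    )
    pairings = tuple((c.context_id, c.option_ids, 30) for c in contexts)
    return TaskDesign(
        design_id="B21",
        variant=variant,
        contexts=contexts,
        test_contexts=test_contexts,
        learning_pairings=pairings,
        test_repeats=30,
        rescale_factor=10.0,
        learn_feedback=learn_fb,
        test_feedback=test_fb,
        presentation=presentation,
    )


def _build_b18(variant: str) -> TaskDesign:
    if variant not in ("1", "2"):
        raise ValueError(f"unknown B18 variant {variant!r}; supported: 1, 2")
    opts = {
        "A": _bern("A", 1, 0, 0.75),
        "B": _bern("B", 1, 0, 0.25),
        "C": _bern("C", 0.1, 0, 0.75),
        "D": _bern("D", 0.1, 0, 0.25),
        "E": _bern("E", 0, -1, 0.75),
        "F": _bern("F", 0, -1, 0.25),
        "G": _bern("G", 0, -0.1, 0.75),
        "H": _bern("H", 0, -0.1, 0.25),
    }
    contexts = (
        ContextSpec("1", (opts["A"], opts["B"])),
        ContextSpec("2", (opts["C"], opts["D"])),
        ContextSpec("3", (opts["E"], opts["F"])),
        ContextSpec("4", (opts["G"], opts["H"])),
    )
    ids = sorted(opts)
    test_contexts = tuple(
        _pair_context(f"{a}{b}", opts[a], opts[b])
        for a, b in itertools.combinations(ids, 2)
    )
    pairings = tuple((c.context_id, c.option_ids, 30) for c in contexts)
    return TaskDesign(
        design_id="B18",
        variant=variant,
        contexts=contexts,
        test_contexts=test_contexts,
        learning_pairings=pairings,
        test_repeats=4,
        rescale_factor=1.0,
        learn_feedback="complete" if variant == "2" else "partial",
        test_feedback="none",
        presentation="interleaved",
        complete_fraction=0.5 if variant == "2" else 1.0,
    )


def _build_g12() -> TaskDesign:
    # 2x2 of best-outcome valence (1/0 vs 0/-1) and favourable-outcome
    # probability (.9 vs .8).
    opts = {
        "A": _bern("A", 1, 0, 0.9),
        "B": _bern("B", 1, 0, 0.1),
        "C": _bern("C", 1, 0, 0.8),
        "D": _bern("D", 1, 0, 0.2),
        "E": _bern("E", 0, -1, 0.9),
        "F": _bern("F", 0, -1, 0.1),
        "G": _bern("G", 0, -1, 0.8),
        "H": _bern("H", 0, -1, 0.2),
    }
    contexts = (
        ContextSpec("1", (opts["A"], opts["B"])),
        ContextSpec("2", (opts["C"], opts["D"])),
        ContextSpec("3", (opts["E"], opts["F"])),
        ContextSpec("4", (opts["G"], opts["H"])),
    )
    ids = sorted(opts)
    test_contexts = tuple(
        _pair_context(f"{a}{b}", opts[a], opts[b])
        for a, b in itertools.combinations(ids, 2)
    )
    pairings = tuple((c.context_id, c.option_ids, 30) for c in contexts)
    return TaskDesign(
        design_id="G12",
        variant="default",
        contexts=contexts,
        test_contexts=test_contexts,
        learning_pairings=pairings,
        test_repeats=4,
        rescale_factor=1.0,
        learn_feedback="partial",
        test_feedback="none",
        presentation="interleaved",
    )


def _build_b22() -> TaskDesign:
    # two learning sessions with fresh stimuli; only session-2 stimuli
    # enter the test phase.  Wide range 14-86, narrow 14-50; trinary
    # contexts add a mid option (50 wide, 32 narrow).
    def session_opts(suffix):
        return {
            "A": _gauss("A" + suffix, 14),
            "B": _gauss("B" + suffix, 50),
            "C": _gauss("C" + suffix, 14),
            "D": _gauss("D" + suffix, 32),
            "E": _gauss("E" + suffix, 50),
            "F": _gauss("F" + suffix, 14),
            "G": _gauss("G" + suffix, 86),
            "H": _gauss("H" + suffix, 14),
            "I": _gauss("I" + suffix, 50),
            "J": _gauss("J" + suffix, 86),
        }

    def session_contexts(suffix):
        o = session_opts(suffix)
        return (
            ContextSpec("1" + suffix, (o["A"], o["B"])),
            ContextSpec("2" + suffix, (o["C"], o["D"], o["E"])),
            ContextSpec("3" + suffix, (o["F"], o["G"])),
            ContextSpec("4" + suffix, (o["H"], o["I"], o["J"])),
        )

    s1 = session_contexts("_s1")
    s2 = session_contexts("")
    contexts = s1 + s2
    s2_opts = [o for c in s2 for o in c.options]
    test_contexts = tuple(
        _pair_context(f"{a.option_id}{b.option_id}", a, b)
        for a, b in itertools.combinations(s2_opts, 2)
    )
    pairings = tuple((c.context_id, c.option_ids, 20) for c in contexts)
    return TaskDesign(
        design_id="B22",
        variant="default",
        contexts=contexts,
        test_contexts=test_contexts,
        learning_pairings=pairings,
        test_repeats=2,
        rescale_factor=100.0,
        learn_feedback="complete",
        test_feedback="none",
        presentation="interleaved",
        session_breaks=(4,),
    )


def _build_m22(design_id: str) -> TaskDesign:
    opts = {
        "L1": _gauss("L1", 14),
        "M1": _gauss("M1", 50),
        "H1": _gauss("H1", 86),
        "L2": _gauss("L2", 14),
        "M2": _gauss("M2", 50),
        "H2": _gauss("H2", 86),
    }
    contexts = (
        ContextSpec("1", (opts["L1"], opts["M1"], opts["H1"])),
        ContextSpec("2", (opts["L2"], opts["M2"], opts["H2"])),
    )
    # the design's crux: M1 co-occurs with L1 (never H1) in binary trials,
    # M2 with H2 (never L2), so M1 wins its comparisons far more often.
    pairings = (
        ("1", ("L1", "M1", "H1"), 20),
        ("1", ("L1", "M1"), 20),
        ("1", ("L1", "H1"), 20),
        ("2", ("L2", "M2", "H2"), 20),
        ("2", ("M2", "H2"), 20),
        ("2", ("L2", "H2"), 20),
    )
    all_opts = [o for c in contexts for o in c.options]
    test_contexts = tuple(
        _pair_context(f"{a.option_id}{b.option_id}", a, b)
        for a, b in itertools.combinations(all_opts, 2)
    )
    return TaskDesign(
        design_id=design_id,
        variant="default",
        contexts=contexts,
        test_contexts=test_contexts,
        learning_pairings=pairings,
        test_repeats=4,
        rescale_factor=100.0,
        learn_feedback="complete",
        test_feedback="none",
        presentation="interleaved",
        rating_repeats=4,
    )


def available_designs() -> dict[str, tuple[str, ...]]:
    """Supported (design_id -> variants) combinations."""
    return {
        "B21": B21_VARIANTS,
        "B18": ("1", "2"),
        "G12": ("default",),
        "B22": ("default",),
        "M22": ("default",),
        "M22R": ("default",),
        "M22B": ("default",),
    }


def build_design(design_id: str, variant: str | None = None) -> TaskDesign:
    """Construct one of the built-in task designs.

    Parameters
    ----------
    design_id : {'B21', 'B18', 'G12', 'B22', 'M22', 'M22R', 'M22B'}
    variant : str, optional
        B21 takes one of the 8 three-letter codes (e.g. ``'CNB'``);
        B18 takes ``'1'`` or ``'2'``; other designs have a single variant.
    """
    if design_id == "B21":
        return _build_b21(variant or "PNI")
    if design_id == "B18":
        return _build_b18(str(variant) if variant is not None else "1")
    if variant not in (None, "default"):
        raise ValueError(f"design {design_id} has no variant {variant!r}")
    if design_id == "G12":
        return _build_g12()
    if design_id == "B22":
        return _build_b22()
    if design_id in ("M22", "M22R", "M22B"):
        return _build_m22(design_id)
    supported = ", ".join(available_designs())
    raise ValueError(f"unknown design {design_id!r}; supported: {supported}")


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _assign_complete_trials(design, trials, rng):
    """B18-exp2 style mixing: complete feedback on a fixed fraction of each
    context's learning trials, assigned uniformly at random per seed."""
    frac = design.complete_fraction
    by_ctx: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        by_ctx.setdefault(t.context_id, []).append(i)
    out = list(trials)
    for idxs in by_ctx.values():
        n_complete = int(round(frac * len(idxs)))
        chosen = rng.choice(len(idxs), size=n_complete, replace=False)
        complete = {idxs[j] for j in chosen}
        for i in idxs:
            fb = "complete" if i in complete else "partial"
            out[i] = replace(out[i], feedback=fb)
    return out


def generate_learning_schedule(design: TaskDesign, seed) -> list[Trial]:
    """Generate the learning-phase trial order.

    Interleaved designs shuffle all pairing repetitions uniformly (within
    each session for multi-session designs); blocked designs keep each
    context's trials contiguous and shuffle the block order.
    """
    rng = _as_rng(seed)
    sections: list[list[tuple[str, tuple[str, ...]]]] = []
    breaks = set(design.session_breaks)
    current: list[tuple[str, tuple[str, ...]]] = []
    for i, (ctx, opts, count) in enumerate(design.learning_pairings):
        if i in breaks and current:
            sections.append(current)
            current = []
        current.extend([(ctx, opts)] * count)
    sections.append(current)

    trials: list[Trial] = []
    for section in sections:
        if design.presentation == "blocked":
            by_ctx: dict[str, list] = {}
            for item in section:
                by_ctx.setdefault(item[0], []).append(item)
            blocks = list(by_ctx.values())
            order = rng.permutation(len(blocks))
            ordered = [item for j in order for item in blocks[j]]
        else:
            idx = rng.permutation(len(section))
            ordered = [section[j] for j in idx]
        trials.extend(
            Trial("learning", ctx, opts, design.learn_feedback)
            for ctx, opts in ordered
        )
    if design.learn_feedback == "complete" and design.complete_fraction < 1.0:
        trials = _assign_complete_trials(design, trials, rng)
    return trials


def generate_test_schedule(design: TaskDesign, seed) -> list[Trial]:
    """Generate the test-phase order: every test pairing ``test_repeats``
    times, shuffled (blocked designs keep pairings contiguous)."""
    rng = _as_rng(seed)
    items = [
        (c.context_id, c.option_ids)
        for c in design.test_contexts
        for _ in range(design.test_repeats)
    ]
    if design.presentation == "blocked":
        by_ctx: dict[str, list] = {}
        for item in items:
            by_ctx.setdefault(item[0], []).append(item)
        blocks = list(by_ctx.values())
        order = rng.permutation(len(blocks))
        ordered = [item for j in order for item in blocks[j]]
    else:
        idx = rng.permutation(len(items))
        ordered = [items[j] for j in idx]
    return [Trial("test", ctx, opts, design.test_feedback) for ctx, opts in ordered]


def generate_rating_schedule(design: TaskDesign, seed) -> list[Trial]:
    """Explicit-rating trials (M22 family): each test-eligible stimulus
    rated ``rating_repeats`` times, in shuffled order."""
    if design.rating_repeats == 0:
        return []
    rng = _as_rng(seed)
    rated = [
        o.option_id
        for c in design.contexts
        if not c.context_id.endswith("_s1")
        for o in c.options
    ]
    items = rated * design.rating_repeats
    idx = rng.permutation(len(items))
    return [
        Trial("rating", design.home_context(items[j]).context_id, (items[j],), "none")
        for j in idx
    ]


def sample_outcomes(trial: Trial, design: TaskDesign, rng) -> dict[str, float]:
    """Draw one outcome per available option (raw units, not rescaled).

    Outcomes are drawn for every available option regardless of the
    feedback regime; unrevealed draws are kept as counterfactual ground
    truth.
    """
    rng = _as_rng(rng)
    out = {}
    for oid in trial.options:
        opt = design.option(oid)
        if opt.kind == "bernoulli":
            out[oid] = opt.high if rng.random() < opt.p_high else opt.low
        else:
            out[oid] = opt.mean + opt.sd * rng.standard_normal()
    return out


def rescale_outcomes(records: list[TrialRecord], design: TaskDesign) -> list[TrialRecord]:
    """Divide all stored outcomes by the design's rescaling factor."""
    f = design.rescale_factor
    if f <= 0:
        raise ValueError("rescale factor must be positive")
    return [
        TrialRecord(
            trial=r.trial,
            choice=r.choice,
            outcomes={k: v / f for k, v in r.outcomes.items()},
            revealed=dict(r.revealed),
        )
        for r in records
    ]
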