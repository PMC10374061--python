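# Methods

## The problem being modelled

In bandit tasks with fixed choice contexts, people learn option values
that are partly *relative*: after learning, an option that was the best
of a low-value pair is often preferred over an objectively better
option that was the worst of a high-value pair.  Two mechanism classes
can produce this:

* **Range adaptation** — outcomes are normalized by the context's
  outcome range before learning;
* **Intrinsic enhancement** — outcomes are mixed with a binary,
  internally generated signal of goal achievement ("did I get the best
  outcome available?").

The package implements both, plus a standard (unbiased) learner, a
win-stay/lose-shift heuristic, and a hybrid actor-critic, inside one
shared architecture, so that they can be compared on equal footing.

## Model equations

All models learn option values Q (initialized at 0) by the delta rule
and choose via softmax with inverse temperature β (separate β per phase
except for the hybrid model, which uses one):

    Q ← Q + α·(target − Q),      P(c) ∝ exp(β·Q(c)).

When counterfactual feedback is shown, revealed unchosen options are
updated with a separate rate α_u.  The models differ only in the
`target`:

* **unbiased**: the rescaled outcome r.
* **wsls**: same, with all learning rates fixed at 1 — after one trial
  the value equals the last outcome, reproducing win-stay/lose-shift.
* **range / range_z**: rr = ((r − r_min)/(r_max − r_min))^z with the
  context's known extremes (z = 1 for the linear model).  Outcomes are
  clipped into [r_min, r_max] first, so rr ∈ [0, 1].
* **intrinsic**: ier = ω·ir + (1 − ω)·r.  The binary intrinsic reward
  for any revealed option is 1 iff its outcome is maximal among the
  outcomes revealed on that trial (ties count for every tied option);
  under partial feedback — where no comparison outcome exists — it is 1
  iff the outcome equals the context's maximum attainable value, which
  learners are assumed to know.  Designs with feedback during the test
  phase fit separate mixtures ω_learn and ω_test.
* **hybrid_ac**: a critic tracks context value V via δ_V = o_c − V(s);
  δ_V updates both V (rate α_critic) and the chosen option's actor
  weight W (rate α_actor), after which the context's weights are
  renormalized by Σ|W| (skipped while all weights are zero, to avoid
  dividing by 0).  The policy is a softmax over H = (1 − h)·W + h·Q,
  where the embedded Q-learner is the unbiased model.  In designs with
  losses, the teaching signal is first passed through the loss-weight
  map o = 1 − d, 0, −d for positive, zero and negative outcomes; the
  same map feeds the embedded Q-learner there, so a single d governs
  gain/loss asymmetry in both modules.

Designs that mix gain and loss-avoidance contexts give the range and
intrinsic models separate chosen-option rates α_gains / α_loss,
selected by the valence of the updated option's home context (not by
the realized outcome's sign), matching the convention of fitting
separate rates per condition.

Outcomes are divided by one rescaling factor per design (10 for B21,
100 for B22/M22, 1 for B18/G12) so that all teaching signals live in
[−1, 1] and β estimates are comparable across designs.  This is a
reparameterization, not a theoretical claim; it also puts the intrinsic
reward (0/1) on the same scale as the largest extrinsic reward.

## Task designs

Each built-in design encodes contexts (2-3 options with Bernoulli or
Gaussian outcome distributions), learning-phase pairing frequencies,
test-phase pairings, feedback regime and presentation order.  Points
worth noting:

* **B21** has 8 variants coded by three letters: learning feedback
  partial/complete, test feedback partial/complete/none (matching the
  learning feedback when present), presentation interleaved/blocked.
  Blocked schedules keep each context's trials contiguous and shuffle
  block order per seed, since no canonical block order is defined.
  The four test contexts recombine the eight learned options into pairs
  with ΔEV 6.75, 2.25, 7.25 and 1.75; "context 8" (EV 2.5 vs 0.75)
  pairs a formerly suboptimal against a formerly optimal option and is
  the classic irrationality probe.
* **B18 / G12** expected values are computed from probabilities ×
  magnitudes (e.g. the 0/−1 context at 90% has EVs −0.1/−0.9); loss
  contexts make `has_losses` true, which switches on α_gains/α_loss
  and the hybrid model's d.  B18 experiment 2 interleaves complete
  feedback on a random, context-balanced half of the learning trials.
* **B22** runs two learning sessions with fresh stimuli (values
  re-initialized); only session-2 stimuli enter the test phase.
* **M22** (and its control M22B / replication M22R, structurally
  identical here) presents two trinary Gaussian contexts (means
  14/50/86, variance 4) where the mid option of context 1 is paired 20
  times with its low option and never its high option, and vice versa
  in context 2; 120 learning trials, 60 test trials (all 15 pairs × 4),
  24 rating trials.  Gaussian ranges use the extreme option *means* as
  r_min/r_max, the stable known quantities.

Trial counts the sources leave open were fixed once as package
defaults: 30 learning trials per context for B21/B18/G12 (120 total,
mirroring the designs that do specify 120), 4 repetitions of each
all-pairs test pairing for B18/G12, and for B22 20 trials per context
per session with 2 repetitions of the 45 session-2 test pairs.

Every trial draws outcomes for *all* available options, storing
unrevealed draws flagged as hidden, so partial-feedback, complete-
feedback and posterior-predictive replay share one data path.

## Fitting and model comparison

Parameters are estimated in unconstrained space with independent
N(0, 6.25) priors; β and z map through `exp` (argument clipped at ±50),
all rates and mixtures through a sigmoid.  The MAP is found with
L-BFGS-B from multiple random starts (default 20 for standalone fits;
the first start is the prior mean) and the model evidence is the
Laplace integral at the mode, with the Hessian obtained by central
finite differences (relative step 1e-3).  A non-positive-definite
Hessian is repaired by flooring eigenvalues at 1e-6 and flagged.  On a
1-D conjugate-Gaussian toy this Laplace evidence matches the exact
marginal to ~1e-11.

Hierarchical comparison treats the candidate model as a random effect:
per-subject evidences (under the current model-specific Gaussian group
priors) and population model frequencies define soft responsibilities;
responsibilities drive an empirical-Bayes update of each model's group
mean/variance (with a weak variance anchor at the top-level prior and a
floor of 1e-3) and a Dirichlet update (concentration 1) of the
frequencies; iteration stops when responsibilities change by less than
`tol` (default 1e-3) or after `max_iter` rounds, in which case the last
state is returned flagged as unconverged.  Restart streams are shared
across models within a subject, so byte-identical candidate models
receive byte-identical fits and split responsibilities exactly in half.
The first-pass (flat-prior) Laplace fits are retained alongside the
hierarchical ones and are the estimates used for posterior-predictive
simulation; the reported responsibilities come from the hierarchical
iteration.

Exceedance probabilities are Monte-Carlo estimates (1e5 Dirichlet
draws) of each model being the most frequent; the *protected* version
mixes them with the uniform null in proportion to the Bayes omnibus
risk, computed from the free energies of the random-effects model and
the equal-frequency null.  This implementation follows the published
contract (responsibilities, frequencies, PXP) but does not promise
numerical equality with any particular toolbox — on simulated cohorts
it is validated by winner selection and responsibility ordering.

At least one deliberately simple strategy (WSLS) is included in the
default comparison sets to absorb variance neither model of interest
explains.

## Synthetic cohorts and what they do (not) show

The ex ante generator draws each model parameter from the prospective
priors: β ~ Gamma(shape 1.2, rate 0.2) (mean 6), learning rates ~
Beta(1.1, 1.1), ω ~ Beta(2, 2), z ~ Gamma(3, 3) (mean 1).  Each named
parameter is drawn independently (e.g. β_learn and β_test each get
their own Gamma draw).  Seeding is hierarchical — master seed →
per-subject streams → schedule/outcome/choice streams — so cohorts are
bit-reproducible and adding subjects never changes existing ones.

Simulated agents reproduce the qualitative signatures of interest:
below-chance transfer choice in B21's context 8 for goal-weighted
learners, and the M22 M1-over-M2 preference that separates the
intrinsic model (difference ≈ 0.12-0.19, > 6 SEM at 100 agents) from
the range model (|difference| within sampling noise of 0).  The
generator emulates choice stochasticity and reward sampling only: it
contains no attention lapses, response-time dynamics, practice or
fatigue effects, and rating responses are a noiseless readout of the
agent's current value estimate.  Passing recovery tests on these
cohorts therefore demonstrates identifiability of the models *given
the model class*, not that human data are free of unmodelled structure.

A note on ω recovery: with generating parameters drawn from the ex
ante priors, a sizeable fraction of agents choose nearly at random
(small β) and carry almost no information about ω.  The split-half
reliability of the per-subject ω estimate on such cohorts is ≈ 0.5,
which caps the attainable true-vs-recovered Spearman correlation near
0.7; measured values across seeds fall around 0.45-0.74.  Recovery of
β is excellent (ρ ≈ 0.95) and the recovered ω correlates positively
with the M1−M2 behavioral signature, as expected.

## Numerical and design choices

* Softmax is computed with a max shift; probabilities sum to 1 within
  1e-12 and are invariant to common value shifts.
* The likelihood replay loop is JIT-compiled (numba) for fitting speed;
  a pure-Python per-trial implementation (`agents.model_step`) drives
  all simulation and is asserted equal to the kernel (atol 1e-12) in
  the test suite, keeping the two routes honest against each other.
* Intrinsic-reward ties (equal revealed outcomes) grant the goal signal
  to every tied option, the direct reading of a strict "worse than"
  comparison.
* No-feedback trials (including the usual no-feedback test phases)
  trigger no learning in any model, including the hybrid critic.
* Unchosen-option updates in trinary complete-feedback trials share a
  single α_u.
* Equal-EV test pairings (e.g. M1 vs M2) have no defined "correct"
  option; correct-rate scoring breaks ties toward the first-listed
  option and the signature analyses use choice rates, which are
  tie-free.
* "Correct" in test-phase scoring is defined by design expected value,
  not by empirically realized outcome means.
* Recovery pipelines default to generating parameters from the ex ante
  priors; recovery from fitted real-data parameters would require the
  original datasets.
* Problem sizes used by the validation runs — 100 agents for ex ante
  cohorts, 50 subjects per generating model for confusion matrices,
  100 subjects for parameter recovery — were chosen as the smallest
  cohorts at which the qualitative outcomes are stable across seeds.

## Known limitations

* The hierarchical routine is an empirical-Bayes approximation, not a
  full variational treatment; group variances are point estimates and
  subject-level uncertainty does not propagate into them.
* The range model assumes known context extremes; the dynamic variant
  that learns r_min/r_max trial-by-trial is not implemented (it has
  been reported both unhelpful and unrecoverable).
* Explicit value ratings are emitted by the simulator but not modelled
  in the likelihood.
* Forced-choice trial variants and designs beyond the five built-ins
  require user-supplied design descriptors (JSON) rather than built-in
  constructors.
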