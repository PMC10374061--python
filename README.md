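# ierl — intrinsically enhanced reinforcement learning

Tools for modelling **context-sensitive valuation** in human
reinforcement learning: the robust finding that the experienced value of
an outcome depends on the alternatives it is presented with, so that an
option learned as "the best of a bad pair" can later be preferred over
an objectively better option from another context.

The package is aimed at computational cognitive scientists who want to
simulate, fit and compare trial-by-trial learning models on multi-armed
bandit tasks with learning and transfer (test) phases.  It provides:

* **Five task designs as data** (`B21`, `B18`, `G12`, `B22`, `M22` with
  its replication/control variants), covering Bernoulli-magnitude and
  Gaussian reward schedules, partial/complete/no feedback, and
  blocked/interleaved presentation, including schedule generators and
  outcome samplers.
* **Five model families** sharing a delta-rule / softmax architecture:

  | model | teaching signal |
  |---|---|
  | `unbiased` | objective outcome `r` |
  | `wsls` | win-stay/lose-shift: `unbiased` with learning rate 1 |
  | `range`, `range_z` | range-normalized `rr = ((r − r_min)/(r_max − r_min))^z` |
  | `intrinsic` | `ier = ω·ir + (1 − ω)·r`, `ir ∈ {0,1}` a goal-achievement signal |
  | `hybrid_ac` | actor-critic weights mixed with Q-values, `H = (1−h)·W + h·Q` |

  The centrepiece is the *intrinsically enhanced* model: the binary
  intrinsic reward `ir` equals 1 exactly when the obtained outcome was
  the best attainable on that trial (the best revealed outcome under
  counterfactual feedback, the context's known maximum under partial
  feedback), and the mixture weight ω measures how much goal achievement
  dominates objective reward.
* **A fitting and comparison pipeline**: per-subject MAP estimation in
  unconstrained space (N(0, 6.25) priors; `exp` links for inverse
  temperatures β and the exponent z, sigmoid links for rates and
  mixtures) with Laplace model evidence, and hierarchical random-effects
  comparison producing per-subject model responsibilities, population
  model frequencies, and protected exceedance probabilities.
* **Validation instruments**: ex ante (prospective) simulation from
  parameter priors, posterior-predictive replay, simulate-and-refit
  confusion matrices, and parameter-recovery rank correlations.

## Worked example

Simulate 100 agents from the ex ante priors on the M22 design — two
three-option contexts with Gaussian outcomes (means 14/50/86, variance
4) in which the mid-value option of context 1 (`M1`) is mostly paired
with a *worse* option while the mid-value option of context 2 (`M2`) is
mostly paired with a *better* one — then summarize test-phase choice
rates and fit one subject:

```python
import ierl

design = ierl.build_design("M22")
cohort, rates = ierl.simulate_ex_ante("intrinsic", design, n_agents=100, seed=7)
print(rates.round(3).to_string(index=False))
```

```
option_id  choice_rate   sem
       M1        0.533 0.013
       L2        0.229 0.012
       M2        0.404 0.011
       H2        0.794 0.013
       L1        0.246 0.013
       H1        0.794 0.013
```

Although `M1` and `M2` have identical objective value (mean 50), the
goal-weighted learner chooses `M1` far more often (0.533 vs 0.404): `M1`
usually *wins* its learning-phase comparisons and therefore accrues
intrinsic reward, `M2` usually loses them.  A range-adaptation learner
(`"range_z"`) shows no such preference — this asymmetry is the design's
discriminating signature.

Fitting a single simulated subject follows the statsmodels idiom:

```python
subject = ierl.SubjectModel(cohort.records[0], design, model="intrinsic")
result = subject.fit(n_restarts=5, seed=0)
print(result.summary())
```

```
Model: intrinsic   design: M22 (default)
Trials: 180   log evidence (Laplace): -63.105   Hessian PD: True
parameter         estimate     std err
alpha_c             0.6772      0.4705
alpha_u             0.8375      0.2098
beta_learn          7.2688      1.3119
beta_test           1.8011      0.6328
omega_learn         0.1052      0.1105
```

`alpha_c`/`alpha_u` are the chosen/unchosen-option learning rates,
`beta_*` the phase-specific softmax inverse temperatures, and
`omega_learn` the intrinsic-reward weight (this subject was generated
with ω = 0.205).  Cohort-level comparison uses
`ierl.HierarchicalModel(datasets, design, models=(...)).fit()`, whose
results carry responsibilities, model frequencies and protected
exceedance probabilities.

A command-line interface wraps the same pipelines:

```bash
ierl simulate --design M22 --model intrinsic --n 100 --seed 7 --out cohort.csv
ierl fit      --models intrinsic --data cohort.csv --design M22 --out fit.json
ierl compare  --models intrinsic,range_z,wsls --data cohort.csv --design M22 --out report.json
ierl recover  --design M22 --models intrinsic,range_z,wsls --n 50 --seed 3 --out confusion.json
ierl summarize --data cohort.csv --design M22 --out summary.csv
```

## Further reading

`docs/methods.md` documents the model equations, the fitting and
comparison machinery, the synthetic-cohort generator and its limits,
and the package's numerical choices.
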