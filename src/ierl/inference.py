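"""Subject-level fitting and hierarchical random-effects model comparison.

Fitting follows the two-stage pipeline standard in computational
cognitive modelling:

1. **Subject level** — each parameter lives on an unconstrained scale
   with a Gaussian prior N(0, 6.25); inverse temperatures and the range
   nonlinearity ``z`` map through ``exp`` onto (0, inf), all rates and
   mixture weights through a sigmoid onto (0, 1).  The maximum a
   posteriori estimate is found by quasi-Newton optimisation from
   multiple random starts and the model evidence is approximated by a
   Laplace integral at the mode.
2. **Group level** — candidate models are compared as random effects:
   each subject is assigned soft responsibilities proportional to
   (model frequency x subject evidence); responsibilities update
   Gaussian group priors per model (empirical Bayes) and a Dirichlet
   posterior over model frequencies; iteration to convergence yields
   model frequencies, exceedance probabilities and the protected
   exceedance probability (exceedance corrected by the Bayes omnibus
   risk that frequency differences arose by chance).

The public surface mirrors statsmodels: :class:`SubjectModel` /
:class:`HierarchicalModel` are built from data and ``fit()`` returns a
results object carrying estimates, uncertainties and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logsumexp, xlogy

from . import agents
from ._likelihood import CompiledDataset, _run_kernel, compile_records, slot_vector
from .designs import TaskDesign, TrialRecord

__all__ = [
    "PRIOR_MEAN",
    "PRIOR_VAR",
    "to_constrained",
    "to_unconstrained",
    "constrain_vector",
    "negative_log_likelihood",
    "laplace_evidence",
    "SubjectFit",
    "fit_map_laplace",
    "SubjectModel",
    "SubjectResults",
    "GroupResult",
    "fit_hbi",
    "HierarchicalModel",
    "protected_exceedance_probability",
]

PRIOR_MEAN = 0.0
PRIOR_VAR = 6.25

_EXP_CAP = 50.0  # |x| bound on the exp link argument, keeps betas finite


def to_constrained(name: str, x: float) -> float:
    """Map an unconstrained fitting variable to the parameter's domain."""
    if agents.link_function(name) == "exp":
        return float(np.exp(np.clip(x, -_EXP_CAP, _EXP_CAP)))
    return float(expit(x))


def to_unconstrained(name: str, value: float) -> float:
    if agents.link_function(name) == "exp":
        return float(np.log(value))
    return float(np.log(value) - np.log1p(-value))


def constrain_vector(names, x) -> dict[str, float]:
    return {n: to_constrained(n, xi) for n, xi in zip(names, x)}


def negative_log_likelihood(
    model_id: str,
    params: dict[str, float],
    records: list[TrialRecord],
    design: TaskDesign,
) -> float:
    """Choice NLL over learning + test trials (constrained-space params)."""
    from ._likelihood import negative_log_likelihood as _nll

    return _nll(model_id, params, records, design)


# ---------------------------------------------------------------------------
# Laplace approximation
# ---------------------------------------------------------------------------


def _fd_hessian(f, x, rel_step=1e-3):
    """Central finite-difference Hessian."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def laplace_evidence(neg_log_joint, x_map, rel_step=1e-3, min_eig=1e-6):
    """Laplace approximation to the log marginal at a mode.

    ``log Z ~ -E(x*) + (k/2) log(2 pi) - (1/2) log det H`` with H the
    Hessian of the negative log joint E at the mode x*.  A non-positive-
    definite Hessian is repaired by flooring its eigenvalues at
    ``min_eig`` and flagged.

    Returns ``(log_evidence, hessian, is_pd)``.
    """
    x_map = np.atleast_1d(np.asarray(x_map, dtype=float))
    k = x_map.size
    H = _fd_hessian(neg_log_joint, x_map, rel_step)
    eigvals, eigvecs = np.linalg.eigh(H)
    is_pd = bool(np.all(eigvals > 0))
    if not is_pd:
        eigvals = np.maximum(eigvals, min_eig)
        H = (eigvecs * eigvals) @ eigvecs.T
    logdet = float(np.sum(np.log(eigvals)))
    log_ev = -float(neg_log_joint(x_map)) + 0.5 * k * np.log(2.0 * np.pi) - 0.5 * logdet
    return log_ev, H, is_pd


# ---------------------------------------------------------------------------
# Subject-level MAP fitting
# ---------------------------------------------------------------------------


@dataclass
class SubjectFit:
    """MAP estimate with Laplace evidence for one subject under one model."""

    model_id: str
    param_names: tuple[str, ...]
    x_map: np.ndarray                # unconstrained space
    params: dict[str, float]         # constrained space
    neg_log_joint: float
    log_evidence: float
    hessian: np.ndarray
    hessian_pd: bool
    n_restarts: int

    @property
    def bse_unconstrained(self) -> np.ndarray:
        """Posterior standard errors in unconstrained space (inverse
        Hessian diagonal at the mode)."""
        cov = np.linalg.inv(self.hessian)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))


def _make_objective(model_id, design, ds: CompiledDataset, names, prior_mean, prior_var):
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    log_norm = 0.5 * np.sum(np.log(2.0 * np.pi * prior_var))

    def neg_log_joint(x):
        params = constrain_vector(names, x)
        slots = slot_vector(model_id, design, params)
        nll, _ = _run_kernel(model_id, slots, ds)
        penalty = 0.5 * np.sum((x - prior_mean) ** 2 / prior_var) + log_norm
        return nll + penalty

    return neg_log_joint


def fit_map_laplace(
    model_id: str,
    records: list[TrialRecord],
    design: TaskDesign,
    n_restarts: int = 20,
    seed=0,
    prior_mean=None,
    prior_var=None,
    x0=None,
    dataset: CompiledDataset | None = None,
    tol: float = 1e-6,
) -> SubjectFit:
    """MAP estimation with Laplace model evidence for one subject.

    Optimizes log prior + log likelihood in unconstrained space with
    L-BFGS-B from ``n_restarts`` random starts (the first start is the
    prior mean; ``x0`` adds a warm start).  Group-level priors other
    than the default N(0, 6.25) may be supplied per parameter.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    names = agents.param_names(model_id, design)
    k = len(names)
    pm = np.full(k, PRIOR_MEAN) if prior_mean is None else np.asarray(prior_mean, float)
    pv = np.full(k, PRIOR_VAR) if prior_var is None else np.asarray(prior_var, float)
    ds = dataset if dataset is not None else compile_records(records, design)
    obj = _make_objective(model_id, design, ds, names, pm, pv)

    rng = np.random.default_rng(seed)
    starts = [pm.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    while len(starts) < n_restarts + (x0 is not None):
        starts.append(pm + np.sqrt(pv) * rng.standard_normal(k))

    best = None
    for s in starts:
        res = optimize.minimize(obj, s, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"objective non-finite at every start for model {model_id!r}")

    log_ev, H, is_pd = laplace_evidence(obj, best.x)
    return SubjectFit(
        model_id=model_id,
        param_names=names,
        x_map=np.atleast_1d(best.x),
        params=constrain_vector(names, np.atleast_1d(best.x)),
        neg_log_joint=float(best.fun),
        log_evidence=float(log_ev),
        hessian=H,
        hessian_pd=is_pd,
        n_restarts=n_restarts,
    )


class SubjectModel:
    """One subject's choice data under one candidate learning model.

    Parameters
    ----------
    records : list of TrialRecord
        The subject's trials in presentation order (raw outcome units).
    design : TaskDesign
    model : str
        One of ``ierl.agents.MODELS``.

    Examples
    --------
    >>> m = SubjectModel(records, design, model="intrinsic")
    >>> res = m.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, records, design: TaskDesign, model: str = "intrinsic"):
        if model not in agents.MODELS:
            raise ValueError(f"unknown model {model!r}")
        self.records = list(records)
        self.design = design
        self.model_id = model
        self.param_names = agents.param_names(model, design)
        self._dataset = compile_records(self.records, design)

    @classmethod
    def from_dataframe(cls, df, design: TaskDesign, model: str = "intrinsic"):
        """Build from a long-format trial DataFrame (one subject)."""
        from .io import records_from_frame

        return cls(records_from_frame(df, design), design, model)

    def loglike(self, params: dict[str, float]) -> float:
        nll, _ = _run_kernel(
            self.model_id, slot_vector(self.model_id, self.design, params), self._dataset
        )
        return -float(nll)

    def fit(self, n_restarts: int = 20, seed=0, **kwargs) -> "SubjectResults":
        sf = fit_map_laplace(
            self.model_id, self.records, self.design,
            n_restarts=n_restarts, seed=seed, dataset=self._dataset, **kwargs
        )
        return SubjectResults(self, sf)


class SubjectResults:
    """MAP fit of one subject; exposes estimates, evidence and summary()."""

    def __init__(self, model: SubjectModel, fit: SubjectFit):
        self.model = model
        self._fit = fit
        self.params = fit.params
        self.x_map = fit.x_map
        self.log_evidence = fit.log_evidence
        self.neg_log_joint = fit.neg_log_joint
        self.hessian_pd = fit.hessian_pd

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors on the constrained scale (delta
        method through the link functions)."""
        se_u = self._fit.bse_unconstrained
        out = {}
        for name, x, s in zip(self._fit.param_names, self.x_map, se_u):
            if agents.link_function(name) == "exp":
                grad = np.exp(np.clip(x, -_EXP_CAP, _EXP_CAP))
            else:
                p = expit(x)
                grad = p * (1.0 - p)
            out[name] = float(s * grad)
        return out

    def simulate(self, n_reps: int = 10, seed=0):
        """Posterior-predictive replay of this subject's trial sequence."""
        from .simulate import posterior_predictive

        return posterior_predictive(
            self.model.model_id, [self.params], [self.model.records],
            self.model.design, n_reps=n_reps, seed=seed,
        )

    def summary(self) -> str:
        fit = self._fit
        bse = self.bse
        lines = [
            f"Model: {fit.model_id}   design: {self.model.design.design_id}"
            f" ({self.model.design.variant})",
            f"Trials: {self.model._dataset.n_trials}   "
            f"log evidence (Laplace): {self.log_evidence:.3f}   "
            f"Hessian PD: {fit.hessian_pd}",
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name in fit.param_names:
            lines.append(f"{name:<14}{self.params[name]:>12.4f}{bse[name]:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Hierarchical model comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupResult:
    """Cohort-level outcome of hierarchical random-effects comparison."""

    model_ids: tuple[str, ...]
    responsibilities: np.ndarray      # (n_subjects, K), rows sum to 1
    frequencies: np.ndarray           # (K,) Dirichlet posterior mean
    dirichlet_alpha: np.ndarray       # (K,)
    exceedance: np.ndarray            # (K,)
    pxp: np.ndarray                   # (K,)
    bor: float
    log_evidence: np.ndarray          # (n_subjects, K) final-iteration matrix
    subject_fits: list                # per model: list[SubjectFit] (hierarchical)
    laplace_fits: list                # per model: list[SubjectFit] (flat priors)
    group_means: list                 # per model: unconstrained mean vector
    group_vars: list
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)

    @property
    def winner(self) -> str:
        return self.model_ids[int(np.argmax(self.frequencies))]

    def summary(self) -> str:
        lines = [
            f"Hierarchical comparison of {len(self.model_ids)} models, "
            f"{self.responsibilities.shape[0]} subjects "
            f"({'converged' if self.converged else 'NOT converged'} "
            f"in {self.n_iter} iterations)",
            f"{'model':<14}{'frequency':>11}{'mean resp.':>12}{'EP':>8}{'PXP':>8}",
        ]
        mean_resp = self.responsibilities.mean(axis=0)
        for i, m in enumerate(self.model_ids):
            lines.append(
                f"{m:<14}{self.frequencies[i]:>11.3f}{mean_resp[i]:>12.3f}"
                f"{self.exceedance[i]:>8.3f}{self.pxp[i]:>8.3f}"
            )
        lines.append(f"Bayes omnibus risk: {self.bor:.3f}   winner: {self.winner}")
        return "\n".join(lines)


def _responsibilities(log_ev, log_freq):
    logw = log_ev + log_freq[None, :]
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def protected_exceedance_probability(
    group=None,
    *,
    alpha=None,
    log_evidence=None,
    responsibilities=None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed=0,
):
    """Protected exceedance probabilities over candidate models.

    Exceedance probabilities are estimated by Monte-Carlo sampling the
    Dirichlet posterior over model frequencies; they are then mixed with
    the uniform null in proportion to the Bayes omnibus risk (BOR), the
    posterior probability that observed frequency differences are due to
    chance.  Accepts either a :class:`GroupResult` or the raw pieces.

    Returns ``(pxp, exceedance, bor)``.
    """
    if group is not None:
        alpha = group.dirichlet_alpha
        log_evidence = group.log_evidence
        responsibilities = group.responsibilities
    alpha = np.asarray(alpha, dtype=float)
    K = alpha.size
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    ep = np.bincount(np.argmax(draws, axis=1), minlength=K) / n_samples

    if log_evidence is None:
        bor = 0.0
    else:
        L = np.asarray(log_evidence, dtype=float)
        r = np.asarray(responsibilities, dtype=float)
        asum = alpha.sum()
        # free energy of the null (equal frequencies)
        f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
        # free energy of the random-effects model
        elogm = digamma(alpha) - digamma(asum)
        a0 = np.full(K, alpha0)
        kl_dir = (
            gammaln(asum) - np.sum(gammaln(alpha))
            - gammaln(a0.sum()) + np.sum(gammaln(a0))
            + np.sum((alpha - a0) * elogm)
        )
        f1 = float(np.sum(r * (L + elogm[None, :])) - np.sum(xlogy(r, r)) - kl_dir)
        bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    pxp = (1.0 - bor) * ep + bor / K
    return pxp, ep, float(bor)


def fit_hbi(
    model_ids,
    datasets,
    design: TaskDesign,
    max_iter: int = 12,
    tol: float = 1e-3,
    seed=0,
    n_restarts_init: int = 5,
    n_restarts_iter: int = 1,
    alpha0: float = 1.0,
    var_floor: float = 1e-3,
) -> GroupResult:
    """Hierarchical random-effects fitting and comparison.

    ``datasets`` is a list of per-subject record lists.  The loop
    alternates (i) per-subject MAP + Laplace evidence under the current
    model-specific group priors, (ii) responsibility updates
    proportional to model frequency x evidence, (iii) responsibility-
    weighted empirical-Bayes updates of each model's group mean and
    variance, and (iv) a Dirichlet update of model frequencies.  The
    first pass uses flat N(0, 6.25) priors; those non-hierarchical
    Laplace fits are retained (``laplace_fits``) for simulation.
    """
    model_ids = tuple(model_ids)
    if len(model_ids) < 2:
        raise ValueError("hierarchical comparison needs >= 2 models")
    if len(datasets) < 2:
        raise ValueError("hierarchical comparison needs >= 2 subjects")
    K = len(model_ids)
    n = len(datasets)
    compiled = [compile_records(recs, design) for recs in datasets]
    ss = np.random.SeedSequence(seed)
    # one restart stream per subject, shared across models: byte-identical
    # candidate models then receive byte-identical fits
    subj_seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(n + 1)]

    names = [agents.param_names(m, design) for m in model_ids]
    pm = [np.zeros(len(nm)) for nm in names]
    pv = [np.full(len(nm), PRIOR_VAR) for nm in names]

    def refit(warm, restarts):
        fits = []
        L = np.zeros((n, K))
        for j, m in enumerate(model_ids):
            fits.append([])
            for i in range(n):
                x0 = warm[j][i].x_map if warm is not None else None
                f = fit_map_laplace(
                    m, datasets[i], design,
                    n_restarts=restarts, seed=subj_seeds[i],
                    prior_mean=pm[j], prior_var=pv[j],
                    x0=x0, dataset=compiled[i],
                )
                fits[j].append(f)
                L[i, j] = f.log_evidence
        return fits, L

    fits, L = refit(None, n_restarts_init)
    laplace_fits = [list(f) for f in fits]
    freq = np.full(K, 1.0 / K)
    resp = _responsibilities(L, np.log(freq))
    alpha = np.full(K, alpha0) + resp.sum(axis=0)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (iii) group update per model
        for j in range(K):
            w = resp[:, j]
            wsum = w.sum()
            X = np.stack([fits[j][i].x_map for i in range(n)])
            mean = (w[:, None] * X).sum(axis=0) / (wsum + 1e-12)
            var = ((w[:, None] * (X - mean) ** 2).sum(axis=0) + PRIOR_VAR * alpha0) / (
                wsum + alpha0
            )
            pm[j] = mean
            pv[j] = np.maximum(var, var_floor)
        # (i) refit under updated priors, warm-started
        fits, L = refit(fits, n_restarts_iter)
        # (ii)+(iv) responsibilities and frequencies
        freq = alpha / alpha.sum()
        new_resp = _responsibilities(L, np.log(freq))
        alpha = np.full(K, alpha0) + new_resp.sum(axis=0)
        delta = float(np.max(np.abs(new_resp - resp)))
        resp = new_resp
        trace.append({"iter": it, "delta": delta, "frequencies": alpha / alpha.sum()})
        if delta < tol:
            converged = True
            break

    freq = alpha / alpha.sum()
    pxp, ep, bor = protected_exceedance_probability(
        alpha=alpha, log_evidence=L, responsibilities=resp,
        alpha0=alpha0, seed=subj_seeds[-1],
    )
    return GroupResult(
        model_ids=model_ids,
        responsibilities=resp,
        frequencies=freq,
        dirichlet_alpha=alpha,
        exceedance=ep,
        pxp=pxp,
        bor=bor,
        log_evidence=L,
        subject_fits=fits,
        laplace_fits=laplace_fits,
        group_means=list(pm),
        group_vars=list(pv),
        converged=converged,
        n_iter=it,
        trace=trace,
    )


class HierarchicalModel:
    """Random-effects comparison of candidate models on a cohort.

    >>> hm = HierarchicalModel(datasets, design, models=("intrinsic", "range_z", "wsls"))
    >>> res = hm.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(self, datasets, design: TaskDesign, models=("intrinsic", "range_z", "wsls")):
        self.datasets = list(datasets)
        self.design = design
        self.model_ids = tuple(models)

    @classmethod
    def from_dataframe(cls, df, design, models=("intrinsic", "range_z", "wsls")):
        from .io import cohort_from_frame

        return cls(list(cohort_from_frame(df, design).values()), design, models)

    def fit(self, **kwargs) -> GroupResult:
        return fit_hbi(self.model_ids, self.datasets, self.design, **kwargs)
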