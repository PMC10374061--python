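"""MAP + Laplace fitting, transforms, and hierarchical comparison."""

import numpy as np
import pytest

from ierl import build_design, simulate_agent, simulate_cohort
from ierl.inference import (
    PRIOR_VAR,
    HierarchicalModel,
    SubjectModel,
    fit_hbi,
    fit_map_laplace,
    laplace_evidence,
    negative_log_likelihood,
    protected_exceedance_probability,
    to_constrained,
    to_unconstrained,
)

UNBIASED = {"alpha_c": 0.3, "alpha_u": 0.3, "beta_learn": 5.0, "beta_test": 5.0}


def test_links_roundtrip():
    for name, value in [("alpha_c", 0.37), ("omega_learn", 0.81), ("h", 0.5)]:
        assert to_constrained(name, to_unconstrained(name, value)) == pytest.approx(value)
    for name, value in [("beta_learn", 4.2), ("z", 0.7)]:
        assert to_constrained(name, to_unconstrained(name, value)) == pytest.approx(value)
    assert 0 < to_constrained("alpha_c", -30.0) < 1
    assert to_constrained("beta_learn", 0.0) == 1.0


def test_nll_uniform_policy(b21_cci):
    """beta = 0 makes every binary choice probability 1/2."""
    recs = simulate_agent("unbiased", UNBIASED, b21_cci, seed=0)
    p0 = {"alpha_c": 0.3, "alpha_u": 0.3, "beta_learn": 0.0, "beta_test": 0.0}
    nll = negative_log_likelihood("unbiased", p0, recs, b21_cci)
    assert nll == pytest.approx(240 * np.log(2), rel=1e-12)


def test_nll_greedy_self_fit(m22):
    p = {"alpha_c": 0.8, "alpha_u": 0.8, "beta_learn": 500.0, "beta_test": 500.0}
    recs = simulate_agent("unbiased", p, m22, seed=4)
    nll = negative_log_likelihood("unbiased", p, recs, m22)
    assert nll / 180 < 0.15  # near-deterministic agreement per trial


def test_nll_order_invariance_when_no_learning(m22):
    recs = simulate_agent("unbiased", UNBIASED, m22, seed=6)
    frozen = {"alpha_c": 0.0, "alpha_u": 0.0, "beta_learn": 2.0, "beta_test": 2.0}
    nll = negative_log_likelihood("unbiased", frozen, recs, m22)
    rng = np.random.default_rng(0)
    perm = [recs[i] for i in rng.permutation(len(recs))]
    assert negative_log_likelihood("unbiased", frozen, perm, m22) == pytest.approx(nll)


def test_laplace_matches_conjugate_marginal():
    """1-D Gaussian toy: Laplace equals the exact marginal likelihood."""
    v0, s2, n = PRIOR_VAR, 1.0, 12
    rng = np.random.default_rng(0)
    y = rng.normal(1.3, np.sqrt(s2), n)

    def neg_log_joint(x):
        th = np.atleast_1d(x)[0]
        return (
            0.5 * np.sum((y - th) ** 2) / s2
            + 0.5 * n * np.log(2 * np.pi * s2)
            + 0.5 * th * th / v0
            + 0.5 * np.log(2 * np.pi * v0)
        )

    x_map = y.sum() / s2 / (n / s2 + 1 / v0)
    log_ev, hessian, is_pd = laplace_evidence(neg_log_joint, [x_map])
    cov = s2 * np.eye(n) + v0 * np.ones((n, n))
    _, logdet = np.linalg.slogdet(cov)
    exact = (
        -0.5 * n * np.log(2 * np.pi)
        - 0.5 * logdet
        - 0.5 * y @ np.linalg.solve(cov, y)
    )
    assert is_pd
    assert abs(log_ev - exact) < 1e-8


def test_zero_trials_map_at_prior_mode(m22):
    fit = fit_map_laplace("intrinsic", [], m22, n_restarts=3, seed=0)
    assert np.allclose(fit.x_map, 0.0, atol=1e-4)
    assert np.isfinite(fit.log_evidence)


def test_alpha_recovery_from_long_series(b21_cci):
    """500+ trials of unbiased behavior pin down the learning rate."""
    gen = {"alpha_c": 0.3, "alpha_u": 0.3, "beta_learn": 5.0, "beta_test": 5.0}
    records = []
    for seed in range(3):  # 3 x 240 trials
        records.extend(simulate_agent("unbiased", gen, b21_cci, seed=seed))
    fit = fit_map_laplace("unbiased", records, b21_cci, n_restarts=5, seed=0)
    assert abs(fit.params["alpha_c"] - 0.3) < 0.1
    assert fit.hessian_pd


def test_subject_model_results(m22, m22_records):
    model = SubjectModel(m22_records, m22, model="intrinsic")
    res = model.fit(n_restarts=5, seed=0)
    assert set(res.params) == set(model.param_names)
    assert all(v > 0 for v in res.bse.values())
    text = res.summary()
    assert "omega_learn" in text and "log evidence" in text
    assert res.log_evidence == pytest.approx(
        -res.neg_log_joint
        + 0.5 * len(model.param_names) * np.log(2 * np.pi)
        - 0.5 * np.linalg.slogdet(res._fit.hessian)[1],
        rel=1e-6,
    )


def test_hbi_self_consistency(m22):
    """A cohort generated by the intrinsic model is attributed to it."""
    rng = np.random.default_rng(0)
    params = [
        {"alpha_c": float(rng.beta(2, 2)), "alpha_u": float(rng.beta(2, 2)),
         "beta_learn": float(rng.gamma(4, 1.5)), "beta_test": float(rng.gamma(4, 1.5)),
         "omega_learn": float(rng.beta(2, 2))}
        for _ in range(20)
    ]
    cohort = simulate_cohort("intrinsic", params, m22, 21)
    group = fit_hbi(("intrinsic", "unbiased", "wsls"), cohort.records, m22, seed=0)
    mean_resp = group.responsibilities.mean(axis=0)
    assert group.model_ids[int(np.argmax(mean_resp))] == "intrinsic"
    assert np.allclose(group.responsibilities.sum(axis=1), 1.0, atol=1e-9)
    assert group.frequencies.sum() == pytest.approx(1.0)
    assert group.pxp.sum() == pytest.approx(1.0, abs=1e-6)
    assert group.winner == "intrinsic"
    assert "intrinsic" in group.summary()


def test_hbi_identical_models_split_responsibility(m22):
    params = [
        {"alpha_c": 0.4, "alpha_u": 0.3, "beta_learn": 6.0, "beta_test": 6.0,
         "omega_learn": w}
        for w in (0.3, 0.5, 0.7, 0.9)
    ]
    cohort = simulate_cohort("intrinsic", params, m22, 9)
    group = fit_hbi(("unbiased", "unbiased"), cohort.records, m22, seed=0, max_iter=4)
    assert np.allclose(group.responsibilities, 0.5, atol=1e-6)
    assert np.allclose(group.frequencies, 0.5, atol=1e-6)
    # protected EP collapses to the uniform null for clones
    assert np.allclose(group.pxp, 0.5, atol=0.02)


def test_hbi_preconditions(m22, m22_records):
    with pytest.raises(ValueError):
        fit_hbi(("intrinsic",), [m22_records, m22_records], m22)
    with pytest.raises(ValueError):
        fit_hbi(("intrinsic", "wsls"), [m22_records], m22)


def test_pxp_dominant_and_symmetric():
    L = np.zeros((12, 3))
    L[:, 0] = 6.0
    resp = np.exp(L - L.max(axis=1, keepdims=True))
    resp /= resp.sum(axis=1, keepdims=True)
    alpha = 1.0 + resp.sum(axis=0)
    pxp, ep, bor = protected_exceedance_probability(
        alpha=alpha, log_evidence=L, responsibilities=resp
    )
    assert pxp[0] > 0.99 and ep[0] > 0.99
    assert pxp.sum() == pytest.approx(1.0, abs=1e-6)

    Ls = np.zeros((12, 4))
    resps = np.full((12, 4), 0.25)
    alphas = 1.0 + resps.sum(axis=0)
    pxps, eps, bors = protected_exceedance_probability(
        alpha=alphas, log_evidence=Ls, responsibilities=resps
    )
    assert np.allclose(pxps, 0.25, atol=0.02)
    assert bors > 0.5  # clearly consistent with the null


def test_hierarchical_model_wrapper(m22):
    params = [
        {"alpha_c": 0.4, "alpha_u": 0.3, "beta_learn": 6.0, "beta_test": 6.0,
         "omega_learn": w}
        for w in (0.3, 0.7)
    ]
    cohort = simulate_cohort("intrinsic", params, m22, 2)
    hm = HierarchicalModel(cohort.records, m22, models=("intrinsic", "wsls"))
    res = hm.fit(seed=0, max_iter=3)
    assert res.responsibilities.shape == (2, 2)
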