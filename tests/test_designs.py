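"""Task-design arithmetic, schedules and outcome sampling."""

import numpy as np
import pytest

from ierl.designs import (
    B21_VARIANTS,
    TaskDesign,
    build_design,
    generate_learning_schedule,
    generate_rating_schedule,
    generate_test_schedule,
    rescale_outcomes,
    sample_outcomes,
)


@pytest.mark.parametrize(
    "design_id,variant,expected",
    [
        ("B21", "CNB", [[7.5, 2.5], [7.5, 2.5], [0.75, 0.25], [0.75, 0.25]]),
        ("B18", "1", [[0.75, 0.25], [0.075, 0.025], [-0.25, -0.75], [-0.025, -0.075]]),
        ("G12", None, [[0.9, 0.1], [0.8, 0.2], [-0.1, -0.9], [-0.2, -0.8]]),
        ("M22", None, [[14, 50, 86], [14, 50, 86]]),
    ],
)
def test_context_expected_values(design_id, variant, expected):
    d = build_design(design_id, variant)
    got = [[d.expected_value(o) for o in c.option_ids] for c in d.contexts]
    assert np.allclose(got, expected)


def test_b21_test_recombinations():
    d = build_design("B21", "PNI")
    devs = sorted(
        abs(d.expected_value(c.option_ids[0]) - d.expected_value(c.option_ids[1]))
        for c in d.test_contexts
    )
    assert devs == [1.75, 2.25, 6.75, 7.25]
    ctx8 = d.context("8")
    assert sorted(d.expected_value(o) for o in ctx8.option_ids) == [0.75, 2.5]


def test_m22_gaussian_options(m22):
    for c in m22.contexts:
        assert all(o.kind == "gaussian" and o.sd == 2.0 for o in c.options)
        assert (c.r_min, c.r_max) == (14, 86)


def test_g12_outcome_coding(g12):
    values = {v for c in g12.contexts for o in c.options for v in (o.high, o.low)}
    assert values == {1, 0, -1}
    probs = {o.p_high for c in g12.contexts for o in c.options}
    assert probs == {0.9, 0.8, 0.1, 0.2}


def test_unknown_design_and_variant_errors():
    with pytest.raises(ValueError, match="B21"):
        build_design("B99")
    with pytest.raises(ValueError, match="CNB"):
        build_design("B21", "XXX")
    with pytest.raises(ValueError, match="supported"):
        build_design("B18", "3")


@pytest.mark.parametrize("variant", B21_VARIANTS)
def test_b21_schedule_counts_and_feedback(variant):
    d = build_design("B21", variant)
    learn = generate_learning_schedule(d, 0)
    test = generate_test_schedule(d, 0)
    assert len(learn) == 120 and len(test) == 120
    assert {t.feedback for t in learn} == {d.learn_feedback}
    assert {t.feedback for t in test} == {d.test_feedback}


def test_m22_schedule_counts(m22):
    learn = generate_learning_schedule(m22, 7)
    test = generate_test_schedule(m22, 7)
    rating = generate_rating_schedule(m22, 7)
    assert (len(learn), len(test), len(rating)) == (120, 60, 24)
    # each pairing type exactly 20 times
    from collections import Counter

    counts = Counter(frozenset(t.options) for t in learn)
    assert set(counts.values()) == {20} and len(counts) == 6
    trinary = [t for t in learn if len(t.options) == 3]
    assert Counter(t.context_id for t in trinary) == {"1": 20, "2": 20}
    # test: all 15 unordered pairs, 4 times each
    pair_counts = Counter(frozenset(t.options) for t in test)
    assert len(pair_counts) == 15 and set(pair_counts.values()) == {4}
    # M1 never with H1, M2 never with L2 during learning
    assert frozenset(("M1", "H1")) not in counts
    assert frozenset(("L2", "M2")) not in counts


def test_schedules_deterministic(m22):
    assert generate_learning_schedule(m22, 42) == generate_learning_schedule(m22, 42)
    assert generate_test_schedule(m22, 42) == generate_test_schedule(m22, 42)


def _n_runs(trials):
    runs = 1
    for a, b in zip(trials, trials[1:]):
        if a.context_id != b.context_id:
            runs += 1
    return runs


def test_b21_blocked_vs_interleaved():
    blocked = build_design("B21", "CNB")
    inter = build_design("B21", "CNI")
    for seed in (0, 1, 2):
        assert _n_runs(generate_learning_schedule(blocked, seed)) == 4
        assert _n_runs(generate_test_schedule(blocked, seed)) == 4
        assert _n_runs(generate_learning_schedule(inter, seed)) > 10


def test_b18_experiment2_mixed_feedback():
    d = build_design("B18", "2")
    learn = generate_learning_schedule(d, 3)
    from collections import Counter

    by_ctx = Counter((t.context_id, t.feedback) for t in learn)
    for ctx in ("1", "2", "3", "4"):
        assert by_ctx[(ctx, "complete")] == 15
        assert by_ctx[(ctx, "partial")] == 15


def test_b22_sessions_and_test_pool():
    d = build_design("B22")
    learn = generate_learning_schedule(d, 0)
    assert len(learn) == 160
    # session 1 stimuli precede session 2 and never reappear
    s1 = [i for i, t in enumerate(learn) if t.context_id.endswith("_s1")]
    s2 = [i for i, t in enumerate(learn) if not t.context_id.endswith("_s1")]
    assert max(s1) < min(s2)
    test = generate_test_schedule(d, 0)
    assert len(test) == 90  # C(10,2) session-2 pairs x 2
    assert all("_s1" not in o for t in test for o in t.options)


def test_sample_outcomes_monte_carlo(b21_cci, m22):
    rng = np.random.default_rng(0)
    ctx1 = [t for t in generate_learning_schedule(b21_cci, 0) if t.context_id == "1"][0]
    draws = np.array(
        [sample_outcomes(ctx1, b21_cci, rng)[ctx1.options[0]] for _ in range(100_000)]
    )
    assert abs(draws.mean() - 7.5) < 0.03
    h_trial = [t for t in generate_learning_schedule(m22, 0) if "H1" in t.options][0]
    g = np.array(
        [sample_outcomes(h_trial, m22, rng)["H1"] for _ in range(100_000)]
    )
    assert abs(g.mean() - 86) < 0.05
    assert abs(g.var() - 4.0) < 0.1


def test_sample_outcomes_deterministic(m22):
    trial = generate_learning_schedule(m22, 0)[0]
    a = sample_outcomes(trial, m22, np.random.default_rng(9))
    b = sample_outcomes(trial, m22, np.random.default_rng(9))
    assert a == b


def test_rescaling(m22_records, m22, b21_cci):
    scaled = rescale_outcomes(m22_records, m22)
    raw = [v for r in m22_records for v in r.outcomes.values()]
    got = [v for r in scaled for v in r.outcomes.values()]
    assert np.allclose(got, np.array(raw) / 100.0)
    assert all(-1 <= v <= 1.0001 for r in scaled[:120] for v in r.outcomes.values())
    assert b21_cci.rescale_factor == 10.0
    # factor-1 designs: identity
    d = build_design("G12")
    assert d.rescale_factor == 1.0


def test_design_json_roundtrip(m22):
    clone = TaskDesign.from_json(m22.to_json())
    assert clone == m22
    assert clone.context("1").r_max == 86
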