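"""Oracle checks for the evaluation statistics: closed forms, exhaustive
enumerations and library cross-checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from carpalkit.evalstats import (
    auc_mann_whitney,
    delong_auc_difference,
    delong_test,
    discrete_frechet,
    distance_strata,
    angle_strata,
    mean_frechet,
    measurement_agreement,
    paired_permutation_test,
    roc_analysis,
    stratified_bootstrap_ci,
)
from carpalkit.geometry import hausdorff_distance


# ---------------------------------------------------------------------------
# agreement


def test_agreement_basics():
    rep = measurement_agreement([1, 2, 3], [1, 1, 1], ci=False)
    assert rep.mae == pytest.approx(1.0)
    assert rep.bias == pytest.approx(1.0)

    rep = measurement_agreement([1.0, 2.0], [1.0, 2.0], ci=False)
    assert rep.mae == 0.0 and rep.loa_lower == 0.0 and rep.loa_upper == 0.0


def test_agreement_closed_form_loa():
    d = np.array([0.2, -0.2, 0.4, -0.4])
    rep = measurement_agreement(d, np.zeros(4), ci=False)
    assert rep.bias == pytest.approx(0.0)
    assert rep.loa_upper == pytest.approx(1.96 * np.std(d, ddof=1), abs=1e-10)
    assert rep.loa_upper == pytest.approx(0.7157, abs=5e-4)
    assert rep.loa_lower == pytest.approx(-0.7157, abs=5e-4)


def test_agreement_requires_pairs():
    with pytest.raises(ValueError):
        measurement_agreement([1.0], [1.0])


def test_agreement_cis_contain_estimates():
    rng = np.random.default_rng(3)
    pred = rng.normal(0, 1, 40)
    truth = pred + rng.normal(0.2, 0.3, 40)
    rep = measurement_agreement(pred, truth, iters=200, seed=1)
    assert rep.mae_ci.low <= rep.mae <= rep.mae_ci.high
    assert rep.bias_ci.low <= rep.bias <= rep.bias_ci.high
    assert rep.loa_lower <= rep.bias <= rep.loa_upper


# ---------------------------------------------------------------------------
# Fréchet


def frechet_by_coupling_enumeration(p, q):
    """Independent oracle: minimise the max pointwise distance over all
    monotone couplings, enumerated explicitly."""
    n, m = len(p), len(q)
    d = np.sqrt(((np.asarray(p)[:, None] - np.asarray(q)[None]) ** 2).sum(-1))
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


def test_frechet_printed_cases():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    assert discrete_frechet(a, a) == 0.0
    assert discrete_frechet(a, a + [0, 1]) == pytest.approx(1.0)
    vee = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    flat = np.array([[0.0, 0.0], [2.0, 0.0]])
    assert discrete_frechet(flat, vee) == pytest.approx(np.sqrt(2))


def test_frechet_matches_enumeration_oracle(rng):
    for _ in range(40):
        p = rng.uniform(-2, 2, (int(rng.integers(1, 8)), 2))
        q = rng.uniform(-2, 2, (int(rng.integers(1, 8)), 2))
        assert discrete_frechet(p, q) == pytest.approx(
            frechet_by_coupling_enumeration(p, q), abs=1e-12)


def test_frechet_properties(rng):
    for _ in range(20):
        p = rng.uniform(-1, 1, (6, 2))
        q = rng.uniform(-1, 1, (5, 2))
        f = discrete_frechet(p, q)
        assert f == pytest.approx(discrete_frechet(q, p))
        assert f >= hausdorff_distance(p, q) - 1e-12
    assert discrete_frechet(p, p) == 0.0


def test_mean_frechet():
    a = [np.array([[0.0, 0.0], [1.0, 0.0]])]
    b = [np.array([[0.0, 2.0], [1.0, 2.0]])]
    mfd, per, ci = mean_frechet(a, b, ci=False)
    assert mfd == pytest.approx(2.0)
    with pytest.raises(ValueError):
        mean_frechet([], [])


# ---------------------------------------------------------------------------
# ROC


def test_roc_trivia():
    rep = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], ci=False)
    assert rep.auc == 1.0 and rep.youden_j == pytest.approx(1.0)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.operating_threshold == 10.0

    rep = roc_analysis([0.9, 0.4, 0.3, 0.5], [1, 1, 0, 0], ci=False)
    assert rep.auc == pytest.approx(0.75)

    rep = roc_analysis([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0], ci=False)
    assert rep.auc == 0.5

    with pytest.raises(ValueError):
        roc_analysis([1, 2], [1, 1])


def test_auc_equals_mann_whitney(rng):
    for _ in range(50):
        n = int(rng.integers(4, 50))
        scores = rng.normal(0, 1, n) + rng.integers(0, 2, n)
        labels = rng.integers(0, 2, n).astype(bool)
        if labels.all() or not labels.any():
            continue
        u = sstats.mannwhitneyu(scores[labels], scores[~labels],
                                alternative="two-sided").statistic
        expect = u / (labels.sum() * (~labels).sum())
        assert auc_mann_whitney(scores, labels) == pytest.approx(expect)


def test_roc_youden_invariant():
    rng = np.random.default_rng(7)
    scores = rng.normal(0, 1, 60) + np.repeat([0, 1.5], 30)
    labels = np.repeat([False, True], 30)
    rep = roc_analysis(scores, labels, ci=False)
    assert rep.youden_j == pytest.approx(rep.sensitivity + rep.specificity - 1)
    assert 0 <= rep.auc <= 1


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_constant_data_zero_width():
    ci = stratified_bootstrap_ci(np.full(20, 3.0), np.mean, iters=50, seed=0)
    assert ci.low == ci.high == 3.0


def test_bootstrap_contains_point_estimate(rng):
    for rep in range(20):
        data = rng.normal(rng.uniform(-2, 2), 1.0, 50)
        ci = stratified_bootstrap_ci(data, np.mean, iters=300, seed=rep)
        assert ci.low - 0.15 <= data.mean() <= ci.high + 0.15


def test_bootstrap_respects_strata(rng):
    data = np.concatenate([np.zeros(10), np.ones(10)])
    strata = (data > 0.5).astype(int)
    ci = stratified_bootstrap_ci(data, np.mean, strata=strata,
                                 iters=100, seed=0)
    # stratum sizes preserved -> the mean is always exactly 0.5
    assert ci.low == ci.high == 0.5
    with pytest.raises(ValueError):
        stratified_bootstrap_ci(data, np.mean, strata=strata[:-1])


def test_strata_rules():
    assert list(distance_strata([0.2, 1.7, 2.0])) == [0, 1, 2]
    assert list(angle_strata([5.0, 17.0, 45.0])) == [0, 1, 4]


# ---------------------------------------------------------------------------
# permutation test


def permutation_oracle(d, statistic=np.mean):
    """Exhaustive sign-flip enumeration."""
    obs = abs(statistic(d))
    hits = 0
    for signs in itertools.product([1.0, -1.0], repeat=len(d)):
        if abs(statistic(np.asarray(signs) * d)) >= obs - 1e-12:
            hits += 1
    return hits / 2 ** len(d)


def test_permutation_identical_samples():
    a = np.array([1.0, 2.0, 3.0])
    assert paired_permutation_test(a, a) == 1.0


def test_permutation_matches_exhaustive_enumeration(rng):
    for n in (3, 5, 8):
        a = rng.normal(0, 1, n)
        b = rng.normal(0.5, 1, n)
        p = paired_permutation_test(a, b, iters=1000, seed=0)
        assert p == pytest.approx(permutation_oracle(a - b), abs=1e-12)


def test_permutation_null_roughly_uniform(rng):
    ps = []
    for rep in range(200):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        ps.append(paired_permutation_test(a, b, iters=200, seed=rep))
    ks = sstats.kstest(ps, "uniform").statistic
    assert ks < 0.15


def test_permutation_rejects_mismatch():
    with pytest.raises(ValueError):
        paired_permutation_test([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_scores():
    rng = np.random.default_rng(5)
    scores = rng.normal(0, 1, 40)
    labels = np.repeat([True, False], 20)
    p, delta = delong_test(scores, scores, labels)
    assert delta == 0.0 and p == 1.0


def test_delong_antisymmetric(rng):
    labels = np.repeat([True, False], 25)
    a = rng.normal(0, 1, 50) + labels
    b = rng.normal(0, 1, 50) + 0.3 * labels
    p_ab, d_ab = delong_test(a, b, labels)
    p_ba, d_ba = delong_test(b, a, labels)
    assert d_ab == pytest.approx(-d_ba)
    assert p_ab == pytest.approx(p_ba)


def test_delong_detects_clear_difference(rng):
    labels = np.repeat([True, False], 100)
    good = rng.normal(0, 0.4, 200) + 2.0 * labels
    bad = rng.normal(0, 1.0, 200)
    p, delta = delong_test(good, bad, labels)
    assert delta > 0.2 and p < 0.01


def test_delong_variance_positive(rng):
    labels = np.repeat([True, False], 30)
    a = rng.normal(0, 1, 60) + labels
    b = rng.normal(0, 1, 60) + 0.5 * labels
    delta, var, p = delong_auc_difference(a, b, labels)
    assert var > 0 and 0 <= p <= 1
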