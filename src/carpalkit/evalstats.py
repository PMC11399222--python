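"""Agreement and detection statistics for the measurement pipeline.

Implements the evaluation stack used to validate automated carpal
measurements against a reference standard: mean absolute error,
Bland-Altman bias and limits of agreement, mean discrete Fréchet distance
between arc polylines, ROC analysis with a Youden-index operating point,
stratified bootstrap confidence intervals, two-sided paired permutation
tests and the DeLong test for correlated AUCs.

Conventions: differences are prediction − truth; limits of agreement are
bias ± 1.96·SD (sample SD, n−1); bootstrap CIs are 2.5/97.5 percentiles
of 1000 stratified resamples; p < 0.05 two-sided is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

DEFAULT_ITERS = 1000


@dataclass
class CI:
    low: float
    high: float

    def as_list(self):
        return [self.low, self.high]


@dataclass
class AgreementReport:
    """Bland-Altman style agreement between prediction and truth."""

    mae: float
    bias: float
    loa_lower: float
    loa_upper: float
    n: int
    mae_ci: CI | None = None
    bias_ci: CI | None = None
    loa_lower_ci: CI | None = None
    loa_upper_ci: CI | None = None

    def to_dict(self) -> dict:
        out = {"mae": self.mae, "bias": self.bias,
               "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
               "n": self.n}
        for k in ("mae", "bias", "loa_lower", "loa_upper"):
            ci = getattr(self, f"{k}_ci")
            if ci is not None:
                out[f"{k}_ci"] = ci.as_list()
        return out


@dataclass
class RocReport:
    auc: float
    operating_threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_pos: int
    n_neg: int
    auc_ci: CI | None = None
    sensitivity_ci: CI | None = None
    specificity_ci: CI | None = None

    def to_dict(self) -> dict:
        out = {"auc": self.auc, "operating_threshold": self.operating_threshold,
               "sensitivity": self.sensitivity, "specificity": self.specificity,
               "youden_j": self.youden_j, "n_pos": self.n_pos, "n_neg": self.n_neg}
        for k in ("auc", "sensitivity", "specificity"):
            ci = getattr(self, f"{k}_ci")
            if ci is not None:
                out[f"{k}_ci"] = ci.as_list()
        return out


# ---------------------------------------------------------------------------
# strata rules


def distance_strata(values, width: float = 1.0) -> np.ndarray:
    """Stratum label per value: 1 mm bins for distances."""
    return np.floor(np.asarray(values, dtype=float) / width).astype(int)


def angle_strata(values, width: float = 10.0) -> np.ndarray:
    """Stratum label per value: 10-degree bins for angles."""
    return distance_strata(values, width)


def binary_strata(labels) -> np.ndarray:
    return np.asarray(labels).astype(int)


# ---------------------------------------------------------------------------
# bootstrap


def stratified_bootstrap_ci(data, statistic, strata=None,
                            iters: int = DEFAULT_ITERS, seed: int = 0,
                            alpha: float = 0.05) -> CI:
    """Percentile bootstrap CI with resampling within strata.

    ``data`` is an (n,) or (n, d) array resampled row-wise; ``statistic``
    maps a resampled array to a scalar.  Stratum sizes are preserved in
    every replicate.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    data = np.asarray(data)
    n = len(data)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata length mismatch")
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty stratum")
    rng = np.random.default_rng(seed)
    vals = np.empty(iters)
    for it in range(iters):
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        vals[it] = statistic(data[idx])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CI(float(lo), float(hi))


# ---------------------------------------------------------------------------
# agreement


def measurement_agreement(pred, truth, ci: bool = True,
                          strata=None, iters: int = DEFAULT_ITERS,
                          seed: int = 0) -> AgreementReport:
    """MAE, Bland-Altman bias and limits of agreement for paired values.

    Differences are pred − truth; LoA = bias ± 1.96·SD(d) with the
    sample (n−1) standard deviation.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D arrays")
    n = len(pred)
    if n < 2:
        raise ValueError("need n >= 2 for limits of agreement")
    d = pred - truth

    def _mae(x):
        return float(np.mean(np.abs(x)))

    def _bias(x):
        return float(np.mean(x))

    def _loa_low(x):
        return float(np.mean(x) - 1.96 * np.std(x, ddof=1))

    def _loa_high(x):
        return float(np.mean(x) + 1.96 * np.std(x, ddof=1))

    report = AgreementReport(mae=_mae(d), bias=_bias(d),
                             loa_lower=_loa_low(d), loa_upper=_loa_high(d), n=n)
    if ci:
        for name, fn in (("mae", _mae), ("bias", _bias),
                         ("loa_lower", _loa_low), ("loa_upper", _loa_high)):
            setattr(report, f"{name}_ci",
                    stratified_bootstrap_ci(d, fn, strata=strata,
                                            iters=iters, seed=seed))
    return report


# ---------------------------------------------------------------------------
# Fréchet


def discrete_frechet(p, q) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic programming over monotone couplings of the two sequences
    (the minimal over couplings of the maximal pointwise distance).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 2 or q.ndim != 2 or len(p) == 0 or len(q) == 0:
        raise ValueError("inputs must be non-empty (n, 2) polylines")
    d = np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2))
    n, m = d.shape
    ca = np.empty((n, m))
    ca[0, 0] = d[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
        row_prev, row = ca[i - 1], ca[i]
        for j in range(1, m):
            row[j] = max(min(row_prev[j], row_prev[j - 1], row[j - 1]), d[i, j])
    return float(ca[-1, -1])


def mean_frechet(pred_arcs, truth_arcs, ci: bool = True,
                 iters: int = DEFAULT_ITERS, seed: int = 0):
    """Mean discrete Fréchet distance over paired polylines.

    Returns ``(mfd, per_pair, ci)``; the CI is a bootstrap CI over cases.
    """
    if len(pred_arcs) != len(truth_arcs) or len(pred_arcs) == 0:
        raise ValueError("need equal non-empty lists of polylines")
    per_pair = np.array([discrete_frechet(p, t)
                         for p, t in zip(pred_arcs, truth_arcs)])
    ci_val = None
    if ci and len(per_pair) >= 2:
        ci_val = stratified_bootstrap_ci(per_pair, lambda x: float(np.mean(x)),
                                         iters=iters, seed=seed)
    return float(per_pair.mean()), per_pair, ci_val


# ---------------------------------------------------------------------------
# ROC / Youden


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the probability of correct ordering with 0.5 tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def roc_analysis(scores, labels, ci: bool = True,
                 iters: int = DEFAULT_ITERS, seed: int = 0) -> RocReport:
    """ROC AUC plus the Youden-index operating point.

    Candidate thresholds are the observed score values; a case is called
    positive when its score >= threshold.  Ties in Youden's J resolve to
    the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    auc = auc_mann_whitney(scores, labels)

    best = None
    for thr in np.unique(scores):
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best

    report = RocReport(auc=auc, operating_threshold=float(thr),
                       sensitivity=sens, specificity=spec, youden_j=j,
                       n_pos=int(len(pos)), n_neg=int(len(neg)))
    if ci:
        data = np.column_stack([scores, labels.astype(float)])
        strata = labels.astype(int)

        def _boot(stat):
            def fn(d):
                s, lab = d[:, 0], d[:, 1].astype(bool)
                return stat(s, lab)
            return stratified_bootstrap_ci(data, fn, strata=strata,
                                           iters=iters, seed=seed)

        report.auc_ci = _boot(auc_mann_whitney)
        report.sensitivity_ci = _boot(
            lambda s, lab: float(np.mean(s[lab] >= thr)))
        report.specificity_ci = _boot(
            lambda s, lab: float(np.mean(s[~lab] < thr)))
    return report


# ---------------------------------------------------------------------------
# permutation test


def paired_permutation_test(errors_a, errors_b, statistic=np.mean,
                            iters: int = DEFAULT_ITERS, seed: int = 0) -> float:
    """Two-sided paired permutation (sign-flip) test.

    The observed statistic is ``statistic(a − b)``; sign patterns of the
    paired differences form the null.  All 2^n patterns are enumerated
    exactly when that is no more work than ``iters`` random flips;
    otherwise random flips with +1 smoothing in numerator and denominator
    (so p can never be 0).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    n = len(d)
    observed = abs(float(statistic(d)))

    if 2 ** n <= iters:
        count = 0
        for bits in range(2 ** n):
            signs = 1 - 2 * ((bits >> np.arange(n)) & 1)
            if abs(float(statistic(d * signs))) >= observed - 1e-12:
                count += 1
        return count / 2 ** n

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(iters, n))
    perm = np.abs(np.apply_along_axis(statistic, 1, signs * d))
    count = int(np.sum(perm >= observed - 1e-12))
    return (count + 1) / (iters + 1)


# ---------------------------------------------------------------------------
# DeLong


def _placements(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v_pos = cmp.mean(axis=1)   # placement of each positive among negatives
    v_neg = cmp.mean(axis=0)   # placement of each negative among positives
    return float(cmp.mean()), v_pos, v_neg


def delong_auc_difference(scores_a, scores_b, labels):
    """DeLong estimate of ΔAUC = AUC_a − AUC_b and its variance.

    Returns ``(delta, variance, p_value)``; the variance comes from the
    placement-value covariance structure, the p from a two-sided normal
    test on the difference.
    """
    labels = np.asarray(labels).astype(bool)
    auc_a, va_pos, va_neg = _placements(scores_a, labels)
    auc_b, vb_pos, vb_neg = _placements(scores_b, labels)
    m, n = len(va_pos), len(va_neg)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 cases per class")
    s_pos = np.cov(np.stack([va_pos, vb_pos]))
    s_neg = np.cov(np.stack([va_neg, vb_neg]))
    var = (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m \
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        p = float(2 * _sstats.norm.sf(abs(delta) / np.sqrt(var)))
    return float(delta), float(var), p


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong test; returns ``(p_value, auc_a - auc_b)``."""
    delta, _, p = delong_auc_difference(scores_a, scores_b, labels)
    return p, delta
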