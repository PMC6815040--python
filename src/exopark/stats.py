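"""Normality-gated comparisons, Spearman correlation, and ROC/AUC inference.

Group and paired comparisons follow the gate convention of the clinical
literature: Shapiro-Wilk on each sample (or on the paired differences) at
alpha = 0.05 routes the comparison to Student's t / paired t when normal
and to Mann-Whitney / Wilcoxon signed-rank otherwise.

AUC is computed through the Mann-Whitney identity ``U / (n1 * n0)`` with
ties counted one half, its confidence interval and curve comparisons
through the DeLong structural-components estimator (the nonparametric
variance of correlated AUCs); curve comparison is reported as
``chi2 = z^2`` with one degree of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "gated_compare",
    "spearman",
    "roc_auc",
    "compare_roc",
    "auc_mann_whitney",
]


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # t | mann_whitney | paired_t | wilcoxon
    statistic: float
    p: float
    n: tuple[int, int]
    mean: tuple[float, float]
    median: tuple[float, float]
    sd: tuple[float, float]
    percent_difference: float  # 100 * (mean_x - mean_y) / mean_y

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (k, 2) array of (fpr, tpr), (0,0) -> (1,1)
    n_pos: int
    n_neg: int
    orientation: int  # +1 as given, -1 if scores were negated to keep AUC >= 0.5
    scores_pos: np.ndarray = field(repr=False)
    scores_neg: np.ndarray = field(repr=False)

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.auc <= hi):
            raise ValueError("CI does not bracket the AUC")


def _normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # constant sample: the gate cannot assert normality
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > alpha


def gated_compare(
    x, y, paired: bool = False, gate_alpha: float = 0.05
) -> ComparisonResult:
    """Compare two samples with a Shapiro-Wilk-gated test choice.

    ``x`` is the test group and ``y`` the reference group (the percent
    difference is relative to ``y``).  Unpaired samples need n >= 3 each,
    paired samples n >= 5 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 5:
            raise ValueError("paired comparison needs >= 5 pairs")
    elif min(x.size, y.size) < 3:
        raise ValueError("unpaired comparison needs >= 3 per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if paired or x[0] == y[0]:
            d = x - y if paired else np.zeros(1)
            if np.all(d == 0):
                # identical constants: no evidence of any difference
                return _result("t" if not paired else "paired_t", 0.0, 1.0, x, y)
        raise ValueError("zero variance in both samples")

    if paired:
        d = x - y
        if np.all(d == 0):
            return _result("paired_t", 0.0, 1.0, x, y)
        if _normal(d, gate_alpha):
            t = sps.ttest_rel(x, y)
            return _result("paired_t", t.statistic, t.pvalue, x, y)
        n = np.count_nonzero(d)
        method = "exact" if n <= 15 else "approx"
        w = sps.wilcoxon(x, y, correction=method == "approx", method=method)
        return _result("wilcoxon", w.statistic, w.pvalue, x, y)
    if _normal(x, gate_alpha) and _normal(y, gate_alpha):
        t = sps.ttest_ind(x, y, equal_var=True)
        return _result("t", t.statistic, t.pvalue, x, y)
    u = sps.mannwhitneyu(x, y, alternative="two-sided")
    return _result("mann_whitney", u.statistic, u.pvalue, x, y)


def _result(test, stat, p, x, y) -> ComparisonResult:
    my = float(np.mean(y))
    pct = 100.0 * (float(np.mean(x)) - my) / my if my != 0 else math.nan
    return ComparisonResult(
        test_used=test,
        statistic=float(stat),
        p=float(p),
        n=(int(x.size), int(y.size)),
        mean=(float(np.mean(x)), my),
        median=(float(np.median(x)), float(np.median(y))),
        sd=(float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            float(np.std(y, ddof=1)) if y.size > 1 else 0.0),
        percent_difference=pct,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 5:
        raise ValueError("Spearman correlation needs n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return math.nan, math.nan
    r = sps.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def auc_mann_whitney(scores_pos, scores_neg) -> float:
    """AUC by the Mann-Whitney identity with ties counted one half."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    n1, n0 = pos.size, neg.size
    alls = np.concatenate([pos, neg])
    mid_all = sps.rankdata(alls)
    mid_pos = sps.rankdata(pos)
    mid_neg = sps.rankdata(neg)
    v10 = (mid_all[:n1] - mid_pos) / n0
    v01 = 1.0 - (mid_all[n1:] - mid_neg) / n1
    return v10, v01


def roc_auc(scores_pos, scores_neg) -> ROCResult:
    """ROC analysis of a score separating a positive from a negative class.

    The orientation is chosen so the reported AUC is >= 0.5 ("case-like
    scores separate from the reference class"); a flipped orientation is
    recorded in ``orientation=-1``.  The 95% CI uses the DeLong variance,
    clipped to [0, 1].
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    orientation = 1
    if auc_mann_whitney(pos, neg) < 0.5:
        pos, neg, orientation = -pos, -neg, -1
    auc = auc_mann_whitney(pos, neg)
    if np.ptp(np.concatenate([pos, neg])) == 0:
        warnings.warn("degenerate scores: both classes constant and equal")
    v10, v01 = _delong_components(pos, neg)
    var = (np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0) + (
        np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0
    )
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    curve = _roc_curve(pos, neg)
    return ROCResult(
        auc=auc, ci95=ci, curve=curve, n_pos=pos.size, n_neg=neg.size,
        orientation=orientation, scores_pos=pos, scores_neg=neg,
    )


def _roc_curve(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Empirical ROC points over all score thresholds, (0,0) to (1,1)."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        tpr.append(float(np.mean(pos >= th)))
        fpr.append(float(np.mean(neg >= th)))
    fpr.append(1.0)
    tpr.append(1.0)
    return np.unique(np.column_stack([fpr, tpr]), axis=0)


def compare_roc(a: ROCResult, b: ROCResult, paired_subjects: bool = False):
    """DeLong test for an AUC difference, reported as chi-square (df = 1).

    With ``paired_subjects`` the two score sets must come from the same
    subjects in the same order; the component covariance then enters the
    variance of the difference.
    """
    if paired_subjects and (a.n_pos != b.n_pos or a.n_neg != b.n_neg):
        raise ValueError("paired comparison requires identical subject sets")
    va10, va01 = _delong_components(a.scores_pos, a.scores_neg)
    vb10, vb01 = _delong_components(b.scores_pos, b.scores_neg)
    if paired_subjects:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / a.n_pos + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / a.n_neg
    else:
        var = (
            (np.var(va10, ddof=1) / a.n_pos if a.n_pos > 1 else 0.0)
            + (np.var(va01, ddof=1) / a.n_neg if a.n_neg > 1 else 0.0)
            + (np.var(vb10, ddof=1) / b.n_pos if b.n_pos > 1 else 0.0)
            + (np.var(vb01, ddof=1) / b.n_neg if b.n_neg > 1 else 0.0)
        )
    diff = a.auc - b.auc
    if diff == 0.0 and var <= 0.0:
        return 0.0, 1.0
    if var <= 0.0:
        return math.inf, 0.0
    z = diff / math.sqrt(var)
    chi2 = z * z
    return float(chi2), float(sps.chi2.sf(chi2, df=1))
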