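"""Evaluation metrics and inferential statistics for model comparison.

Covers everything needed to reproduce the study's reporting surface:
confusion-matrix metrics (ACC/SEN/SPE/PPV/NPV), ROC curves and AUC,
the DeLong test for paired AUCs, exact McNemar tests for paired
accuracies, uncorrected Pearson chi-square tests, Student's t from
summary statistics, and Cohen's kappa with a large-sample confidence
interval and the conventional agreement bins (slight <= 0.20,
fair <= 0.40, moderate <= 0.60, substantial <= 0.80, almost perfect
<= 1.00).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from kernrad.errors import (
    DataError,
    DegenerateComparisonError,
    LabelError,
)


def safe_delong_test(labels, scores_a, scores_b, positive_class=None) -> "TestResult":
    """DeLong test, degrading to a p=NaN note when the difference is degenerate."""
    try:
        return delong_test(labels, scores_a, scores_b, positive_class)
    except DegenerateComparisonError:
        return TestResult(
            statistic=float("nan"), p=float("nan"), method="DeLong",
            note="degenerate: zero variance of the AUC difference",
        )

KAPPA_BINS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class MetricsReport:
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    auc: float | None = None
    threshold: float | None = None
    positive_label: object = None
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    method: str = ""
    note: str = ""


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    interpretation: str
    p_observed: float
    p_chance: float


def confusion_metrics(labels, predictions, positive_class) -> MetricsReport:
    """ACC/SEN/SPE/PPV/NPV from aligned binary labels and predictions.

    Ratios with a zero denominator (e.g. PPV of an all-negative predictor)
    are reported as NaN rather than zero.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise DataError("empty evaluation input")
    if labels.shape != predictions.shape:
        raise DataError("labels and predictions are misaligned")
    pos = labels == positive_class
    ppos = predictions == positive_class
    tp = int(np.sum(pos & ppos))
    fp = int(np.sum(~pos & ppos))
    fn = int(np.sum(pos & ~ppos))
    tn = int(np.sum(~pos & ~ppos))

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return MetricsReport(
        acc=(tp + tn) / labels.size,
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        positive_label=positive_class,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def roc_points(labels, scores, positive_class):
    """ROC curve points (fpr, tpr, threshold) over all score thresholds."""
    y = (np.asarray(labels) == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise LabelError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, scores)
    return fpr, tpr, thr


def roc_auc(labels, scores, positive_class) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    y = (np.asarray(labels) == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise LabelError("AUC needs both classes present")
    return float(roc_auc_score(y, scores))


def youden_threshold(labels, scores, positive_class) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_points(labels, scores, positive_class)
    return float(thr[np.argmax(tpr - fpr)])


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """DeLong structural components (placement values) for one model."""
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y]
    cmp = (pos_scores[:, None] > neg_scores[None, :]).astype(float)
    cmp += 0.5 * (pos_scores[:, None] == neg_scores[None, :])
    v10 = cmp.mean(axis=1)  # per positive subject
    v01 = cmp.mean(axis=0)  # per negative subject
    return v10, v01


def delong_test(labels, scores_a, scores_b, positive_class=None) -> TestResult:
    """DeLong test comparing two correlated AUCs on the same subjects.

    Uses the placement-value covariance estimate; the statistic is
    z = (AUC_A - AUC_B) / SE with a two-sided normal p-value.
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if positive_class is None:
        positive_class = np.unique(labels)[-1]
    pos = labels == positive_class
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise LabelError("DeLong test needs both classes present")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k] = _placements(s[pos], s[~pos])
        aucs[k] = v10[k].mean()
    s10 = np.cov(v10)  # 2x2 covariance of positive placements
    s01 = np.cov(v01)
    contrast = np.array([1.0, -1.0])
    var = contrast @ s10 @ contrast / m + contrast @ s01 @ contrast / n
    if var <= 1e-16:
        raise DegenerateComparisonError("zero variance of the AUC difference")
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return TestResult(
        statistic=float(z), p=float(2 * sps.norm.sf(abs(z))), method="DeLong"
    )


def mcnemar_test(correct_a, correct_b) -> TestResult:
    """Exact McNemar test on paired correctness indicators.

    The statistic reported is the smaller discordant count; the p-value is
    the two-sided exact binomial tail on the discordant pairs.
    """
    a = np.asarray(correct_a, bool)
    b = np.asarray(correct_b, bool)
    if a.shape != b.shape or a.size == 0:
        raise DataError("paired correctness vectors are misaligned or empty")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        return TestResult(
            statistic=0.0, p=1.0, method="McNemar (exact)",
            note="no discordant pairs",
        )
    table = [[int(np.sum(a & b)), n01], [n10, int(np.sum(~a & ~b))]]
    res = _sm_mcnemar(table, exact=True)
    return TestResult(
        statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        method="McNemar (exact)",
    )


def pearson_chi_square(table) -> TestResult:
    """Uncorrected Pearson chi-square test of independence on an r x c table."""
    t = np.asarray(table, float)
    if (t < 0).any():
        raise DataError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("table has a zero margin")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(
        statistic=float(chi2), p=float(p), df=float(dof), method="Pearson chi-square"
    )


def t_from_summary(
    mean1, sd1, n1, mean2, sd2, n2, variant: str = "pooled"
) -> TestResult:
    """Two-sample t-test from summary statistics (pooled Student or Welch)."""
    if n1 < 2 or n2 < 2:
        raise DataError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise DataError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(statistic=0.0, p=1.0, df=n1 + n2 - 2, method="t")
        raise DegenerateComparisonError("zero variance with unequal means")
    equal_var = variant == "pooled"
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = n1 + n2 - 2
    else:
        a, b = sd1**2 / n1, sd2**2 / n2
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    return TestResult(
        statistic=float(t), p=float(p), df=float(df),
        method="Student t" if equal_var else "Welch t",
    )


def kappa_bin(kappa: float) -> str:
    for cut, name in KAPPA_BINS:
        if kappa <= cut + 1e-12:
            return name
    return KAPPA_BINS[-1][1]


def cohen_kappa(table) -> KappaResult:
    """Cohen's kappa from a square agreement table, with 95% CI.

    The standard error is the large-sample (Fleiss-Cohen-Everitt)
    formula; the interpretation bin follows the conventional cutpoints.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise DataError("agreement table must be square")
    n = t.sum()
    if n == 0:
        raise DataError("empty agreement table")
    p = t / n
    po = float(np.trace(p))
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    pe = float(rows @ cols)
    if abs(1 - pe) < 1e-12:
        raise DegenerateComparisonError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)

    # large-sample variance (Fleiss, Cohen & Everitt 1969)
    k = t.shape[0]
    i = np.arange(k)
    term1 = sum(
        p[a, a] * (1 - (rows[a] + cols[a]) * (1 - kappa)) ** 2 for a in i
    )
    term2 = (1 - kappa) ** 2 * sum(
        p[a, b] * (cols[a] + rows[b]) ** 2 for a in i for b in i if a != b
    )
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = kappa - 1.96 * se, kappa + 1.96 * se
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(lo),
        ci_high=float(hi),
        interpretation=kappa_bin(kappa),
        p_observed=po,
        p_chance=pe,
    )
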