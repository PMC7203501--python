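"""Discrimination and clinical-utility analyses.

Implements ROC-AUC with DeLong structural-component variance and the
paired DeLong test, the Youden-index cutoff, stratified 10-fold
cross-validated precision-recall summaries, decision-curve net benefit,
and the univariate two-sample t and 2x2 chi-square comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RocResult",
    "PairedDeLong",
    "PrCvResult",
    "DcaCurve",
    "roc_auc_delong",
    "delong_paired_test",
    "pr_curve_cv",
    "dca_net_benefit",
    "recalibrate_scores",
    "ttest_groups",
    "chi2_2x2",
]


# ----------------------------------------------------------------- DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (V10, V01) and the Mann-Whitney AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    variance: float
    ci95: Tuple[float, float]
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float


def roc_auc_delong(scores, labels) -> RocResult:
    """ROC curve, DeLong AUC variance/CI and the Youden-index cutoff.

    Ties are handled with midranks; the Youden cutoff maximises
    sensitivity + specificity - 1 over the observed thresholds, ties
    broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # roc_curve thresholds are descending; the smallest index among the
    # maximisers has the highest threshold = highest specificity
    pick = int(best.min())
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=float(auc),
        variance=float(var),
        ci95=ci,
        youden_cutoff=float(thr[pick]),
        youden_sensitivity=float(tpr[pick]),
        youden_specificity=float(1.0 - fpr[pick]),
    )


@dataclass
class PairedDeLong:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p_value: float
    ci95: Tuple[float, float]


def delong_paired_test(scores_a, scores_b, labels) -> PairedDeLong:
    """DeLong comparison of two correlated AUCs on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise ValueError("scores_a, scores_b and labels must have equal length")

    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    var = max(var, 0.0)
    if var > 0:
        z = delta / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = 0.0
        p = 1.0
    half = 1.959963984540054 * np.sqrt(var)
    return PairedDeLong(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=float(delta),
        variance=var,
        z=float(z),
        p_value=float(p),
        ci95=(float(delta - half), float(delta + half)),
    )


# -------------------------------------------------------- PR curve with CV


@dataclass
class PrCvResult:
    fold_curves: List[Tuple[np.ndarray, np.ndarray]]  # (precision, recall)
    fold_average_precision: List[float]
    mean_precision: float
    n_folds_used: int
    n_folds_skipped: int


def pr_curve_cv(scores, labels, n_folds: int = 10, seed: int = 0) -> PrCvResult:
    """Per-fold precision-recall curves of a fixed score.

    Folds are stratified on the labels; the summary ``mean_precision``
    is the unweighted mean of the per-fold average precision.  Folds
    without any event are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    curves, aps = [], []
    skipped = 0
    for _, te in skf.split(scores.reshape(-1, 1), labels):
        y, s = labels[te], scores[te]
        if y.sum() == 0:
            skipped += 1
            continue
        prec, rec, _ = precision_recall_curve(y, s)
        curves.append((prec, rec))
        aps.append(float(average_precision_score(y, s)))
    if skipped:
        warnings.warn(f"{skipped} folds had no events and were skipped")
    return PrCvResult(
        fold_curves=curves,
        fold_average_precision=aps,
        mean_precision=float(np.mean(aps)) if aps else float("nan"),
        n_folds_used=len(aps),
        n_folds_skipped=skipped,
    )


# ------------------------------------------------------------------- DCA


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray


def dca_net_benefit(probabilities, labels, thresholds) -> DcaCurve:
    """Decision-curve net benefit of a probability (or binary policy).

    ``net_benefit(pt) = TP/n - (FP/n) * pt / (1 - pt)`` with treatment
    assigned when the predicted probability is >= pt.  A 0/1 vector acts
    as a fixed policy (treat-if-flagged) at every threshold.
    """
    prob = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    nb_model = np.empty_like(thresholds)
    nb_all = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        treat = prob >= pt
        tp = np.sum(treat & (labels == 1)) / n
        fp = np.sum(treat & (labels == 0)) / n
        w = pt / (1.0 - pt)
        nb_model[i] = tp - fp * w
        nb_all[i] = prevalence - (1.0 - prevalence) * w
    return DcaCurve(
        thresholds=thresholds,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=np.zeros_like(thresholds),
    )


def recalibrate_scores(scores, labels) -> np.ndarray:
    """Map a raw linear score to event probabilities.

    One-variable unpenalised logistic regression of the outcome on the
    score, fitted on the evaluated set itself (the DCA probability
    mapping for raw scores).
    """
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    model = LogisticRegression(C=np.inf, max_iter=1000)
    model.fit(scores, np.asarray(labels, dtype=int))
    return model.predict_proba(scores)[:, 1]


# --------------------------------------------------------- simple testing


def ttest_groups(
    a=None,
    b=None,
    *,
    stats_a: Optional[Tuple[int, float, float]] = None,
    stats_b: Optional[Tuple[int, float, float]] = None,
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Two-sided two-sample t-test from raw vectors or (n, mean, sd).

    Both the pooled-variance and Welch variants are available via
    ``equal_var``.
    """
    if stats_a is not None or stats_b is not None:
        if stats_a is None or stats_b is None:
            raise ValueError("provide summary statistics for both groups")
        (na, ma, sa), (nb, mb, sb) = stats_a, stats_b
        if na < 2 or nb < 2:
            raise ValueError("need n >= 2 per group")
        if sa == 0 and sb == 0:
            raise ValueError("zero variance in both groups")
        res = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(table, correction: bool = False) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1.

    No continuity correction by default (switchable).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in the 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)
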