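"""Segmentation scores and agreement/repeatability statistics.

Overlap between masks is measured by the Jaccard coefficient (IoU);
Dice/F1 follows from the identity F1 = 2*IoU / (1 + IoU).  Multiclass
segmentations are scored per class and combined into a support-weighted
IoU (weights = ground-truth voxel counts).  Classifier quality uses
balanced accuracy, the mean of per-class true-positive rates.

Test–retest repeatability of paired measurements is summarised by the
coefficient of variation

    CoV = sigma_sm / mu_pool * 100%,   sigma_sm = sqrt(2) * sigma_diff,

where sigma_diff is the sample SD of the paired differences (the
single-measurement SD sigma_sm absorbs the sqrt(2) because a difference
of two equally noisy measurements has sqrt(2) times their SD), and
mu_pool is the mean of all measurements.  Agreement between two methods
uses Bland–Altman analysis: mean difference, limits of agreement
mu_d +/- z*SD, and their confidence intervals, with a Shapiro–Wilk
normality check on the differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import CompartmentLabelMap
from .errors import DomainError, ParameterError, ShapeError

__all__ = [
    "SegmentationScore",
    "ClassReport",
    "RepeatabilityReport",
    "AgreementReport",
    "iou",
    "dice_from_iou",
    "multiclass_scores",
    "classification_report",
    "repeatability",
    "bland_altman",
    "r_squared",
]

TISSUE_CLASSES = (1, 2, 3)


@dataclass
class SegmentationScore:
    per_class_iou: dict
    per_class_f1: dict
    weighted_iou: float
    whole_mask_iou: float
    supports: dict
    missing_classes: list = field(default_factory=list)


@dataclass
class ClassReport:
    balanced_accuracy: float
    recall: dict
    precision: dict
    undefined_precision: list = field(default_factory=list)


@dataclass
class RepeatabilityReport:
    mean_difference: float
    sigma_diff: float
    sigma_sm: float
    mu_pool: float
    cov_percent: float
    t_statistic: float
    p_value: float
    normality_p: float
    n_pairs: int


@dataclass
class AgreementReport:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    ci_mean: tuple
    ci_loa_lower: tuple
    ci_loa_upper: tuple
    shapiro_p: float
    loa_z: float
    n: int


# ---------------------------------------------------------------------------
# overlap scores
# ---------------------------------------------------------------------------

def iou(a, b) -> float:
    """Jaccard coefficient |a AND b| / |a OR b| of two boolean grids.

    Two empty masks agree perfectly on absence: defined as 1.0 (warned).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice_from_iou(value: float) -> float:
    """Dice/F1 coefficient from a Jaccard value: 2*IoU / (1 + IoU)."""
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"IoU must lie in [0, 1]; got {value}")
    return 2.0 * value / (1.0 + value)


def multiclass_scores(pred: CompartmentLabelMap, truth: CompartmentLabelMap) -> SegmentationScore:
    """Per-class IoU/F1 over cortex/medulla/pelvis plus support-weighted IoU.

    Classes absent from the ground truth are excluded from the weighting
    and flagged.  The whole-mask IoU compares the nonzero supports.
    """
    p, t = pred.data, truth.data
    if p.shape != t.shape:
        raise ShapeError("prediction and truth grids differ")
    per_iou, per_f1, supports, missing = {}, {}, {}, []
    for cls in TISSUE_CLASSES:
        support = int((t == cls).sum())
        supports[cls] = support
        if support == 0:
            missing.append(cls)
            continue
        score = iou(p == cls, t == cls)
        per_iou[cls] = score
        per_f1[cls] = dice_from_iou(score)
    total = sum(supports[c] for c in per_iou)
    weighted = sum(per_iou[c] * supports[c] for c in per_iou) / total if total else float("nan")
    return SegmentationScore(
        per_class_iou=per_iou,
        per_class_f1=per_f1,
        weighted_iou=float(weighted),
        whole_mask_iou=iou(p > 0, t > 0),
        supports=supports,
        missing_classes=missing,
    )


def classification_report(y_true, y_pred) -> ClassReport:
    """Balanced accuracy (mean of per-class recalls) plus recall/precision per class."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    recall, precision, undefined = {}, {}, []
    for cls in classes:
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        recall[cls] = tp / (tp + fn)
        if tp + fp == 0:
            precision[cls] = 0.0
            undefined.append(cls)
        else:
            precision[cls] = tp / (tp + fp)
    return ClassReport(
        balanced_accuracy=float(np.mean(list(recall.values()))),
        recall={int(k): float(v) for k, v in recall.items()},
        precision={int(k): float(v) for k, v in precision.items()},
        undefined_precision=[int(c) for c in undefined],
    )


# ---------------------------------------------------------------------------
# repeatability and agreement
# ---------------------------------------------------------------------------

def repeatability(m1, m2) -> RepeatabilityReport:
    """Test–retest repeatability of paired measurements.

    sigma_diff is the (n-1) sample SD of the paired differences,
    sigma_sm = sqrt(2)*sigma_diff the single-measurement SD, and
    CoV = sigma_sm / mu_pool * 100.  A paired two-sided Student t-test
    and a Shapiro–Wilk normality p-value for the differences are
    attached.
    """
    m1 = np.asarray(m1, dtype=float).ravel()
    m2 = np.asarray(m2, dtype=float).ravel()
    if m1.shape != m2.shape:
        raise ShapeError("paired measurements must have equal length")
    if m1.size < 3:
        raise ParameterError("repeatability requires at least 3 pairs")
    diffs = m2 - m1
    mu_pool = float(np.concatenate([m1, m2]).mean())
    if mu_pool == 0:
        raise DomainError("pooled mean is zero; CoV undefined")
    sigma_diff = float(diffs.std(ddof=1))
    sigma_sm = float(np.sqrt(2.0) * sigma_diff)
    if np.allclose(diffs, diffs[0]):
        t_stat, p_val = (0.0, 1.0) if np.allclose(diffs, 0) else (np.inf, 0.0)
        normality_p = 1.0
    else:
        t_stat, p_val = stats.ttest_rel(m2, m1)
        normality_p = float(stats.shapiro(diffs).pvalue)
    return RepeatabilityReport(
        mean_difference=float(diffs.mean()),
        sigma_diff=sigma_diff,
        sigma_sm=sigma_sm,
        mu_pool=mu_pool,
        cov_percent=float(sigma_sm / abs(mu_pool) * 100.0),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        normality_p=normality_p,
        n_pairs=int(m1.size),
    )


def bland_altman(x, y, loa_z: float = 1.96) -> AgreementReport:
    """Bland–Altman agreement between two measurement series.

    Differences d = x - y; limits of agreement mu_d +/- loa_z*SD(d);
    95% confidence intervals of the mean difference and of each limit
    via the standard large-sample formulas (t quantiles, SE of a limit
    = SD*sqrt(1/n + loa_z^2 / (2(n-1)))).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ShapeError("series must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError("Bland–Altman requires at least 3 pairs")
    d = x - y
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = mu - loa_z * sd, mu + loa_z * sd
    t_crit = stats.t.ppf(0.975, n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + loa_z**2 / (2.0 * (n - 1)))
    shapiro_p = 1.0 if np.allclose(d, d[0]) else float(stats.shapiro(d).pvalue)
    return AgreementReport(
        mean_difference=mu,
        sd_difference=sd,
        loa_lower=float(loa_lo),
        loa_upper=float(loa_hi),
        ci_mean=(mu - t_crit * se_mean, mu + t_crit * se_mean),
        ci_loa_lower=(loa_lo - t_crit * se_loa, loa_lo + t_crit * se_loa),
        ci_loa_upper=(loa_hi - t_crit * se_loa, loa_hi + t_crit * se_loa),
        shapiro_p=shapiro_p,
        loa_z=loa_z,
        n=n,
    )


def r_squared(x, y) -> float:
    """Coefficient of determination of the least-squares line y ~ x."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.rvalue**2)
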