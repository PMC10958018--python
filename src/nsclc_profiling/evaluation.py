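"""ROC machinery: weighted curves, fold averaging, rejection analysis.

The ROC conventions here follow the cross-validated ensemble design: each
fold yields a step ROC curve over its own score thresholds; folds are
aggregated by evaluating every fold's true/false positive rates on the
union of all fold thresholds and averaging per threshold, with the AUC
computed on the mean curve afterwards. Sample weights (e.g. the majority
size) enter both the numerator and denominator of the weighted TPR/FPR.
Rejection analysis withholds samples whose majority size falls below a
threshold and re-aggregates the ROC on the retained samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsemblePredictions

__all__ = [
    "RocCurve",
    "RocSummary",
    "roc_curve",
    "aggregate_roc_folds",
    "rejection_analysis",
    "ensemble_roc",
]


@dataclass
class RocCurve:
    """Step ROC curve with the raw inputs retained for re-evaluation."""

    thresholds: np.ndarray  # descending; +inf first
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)


@dataclass
class RocSummary:
    """Fold-averaged operating points and AUC."""

    thresholds: np.ndarray
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    auc: float
    auc_sd: float
    n_folds: int
    weighting: str = "none"
    rejection_threshold: float | None = None
    fraction_rejected: float = 0.0


def _rates_at(
    thresholds: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted TPR/FPR of the calls ``score >= t`` for each threshold."""
    pos = labels == 1.0
    w_pos = weights[pos].sum()
    w_neg = weights[~pos].sum()
    calls = scores[None, :] >= thresholds[:, None]  # (T, n)
    tpr = (calls[:, pos] * weights[pos]).sum(axis=1) / w_pos
    fpr = (calls[:, ~pos] * weights[~pos]).sum(axis=1) / w_neg
    return fpr, tpr


def roc_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> RocCurve:
    """ROC curve over all operating points, with optional sample weights.

    Thresholds are the unique scores (plus +inf), samples at exactly the
    threshold count as positive calls, and the AUC is the trapezoidal
    integral — equal, unweighted, to the Mann-Whitney pairwise statistic
    with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if sample_weights is None:
        weights = np.ones_like(scores)
    else:
        weights = np.asarray(sample_weights, dtype=float)
        if (weights < 0).any():
            raise ValueError("sample weights must be nonnegative")
    pos = labels == 1.0
    if weights[pos].sum() <= 0 or weights[~pos].sum() <= 0:
        raise ValueError("both classes must be present with positive total weight")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    fpr, tpr = _rates_at(thresholds, scores, labels, weights)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc, scores, labels, weights)


def aggregate_roc_folds(curves: list[RocCurve]) -> RocSummary:
    """Average per-fold TPR/FPR on the union of all fold thresholds.

    Each fold's step curve is re-evaluated exactly (from its retained
    scores) at every threshold in the union; the summary AUC integrates the
    mean curve, and ``auc_sd`` is the standard deviation of the individual
    fold AUCs.
    """
    if not curves:
        raise ValueError("no fold curves supplied")
    thresholds = np.unique(np.concatenate([c.thresholds for c in curves]))[::-1]
    fprs, tprs = [], []
    for c in curves:
        fpr, tpr = _rates_at(thresholds, c.scores, c.labels, c.weights)
        fprs.append(fpr)
        tprs.append(tpr)
    fprs = np.vstack(fprs)
    tprs = np.vstack(tprs)
    mean_fpr = fprs.mean(axis=0)
    mean_tpr = tprs.mean(axis=0)
    fold_aucs = np.asarray([c.auc for c in curves])
    return RocSummary(
        thresholds=thresholds,
        mean_fpr=mean_fpr,
        mean_tpr=mean_tpr,
        sd_tpr=tprs.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean_tpr),
        auc=float(np.trapezoid(mean_tpr, mean_fpr)),
        auc_sd=float(fold_aucs.std(ddof=1)) if len(curves) > 1 else 0.0,
        n_folds=len(curves),
    )


def _fold_curves(
    preds: list[EnsemblePredictions],
    min_majority_size: float = 0.5,
    weighted: bool = False,
) -> tuple[list[RocCurve], int, int]:
    curves = []
    kept = total = 0
    for p in preds:
        if p.true_label is None:
            raise ValueError("true labels required")
        retain = p.majority_size >= min_majority_size
        total += retain.size
        scores = p.aggregated_score[retain]
        labels = p.true_label[retain]
        if retain.sum() < 2 or labels.min() == labels.max():
            warnings.warn(
                f"fold {p.fold}: fewer than 2 samples or a single class retained "
                f"at majority-size threshold {min_majority_size}; fold skipped",
                stacklevel=2,
            )
            continue
        kept += int(retain.sum())
        w = p.majority_size[retain] if weighted else None
        curves.append(roc_curve(scores, labels, w))
    return curves, kept, total


def ensemble_roc(
    preds: list[EnsemblePredictions], weighted: bool = False
) -> RocSummary:
    """Fold-aggregated ROC of ensemble aggregated scores (LUAD axis),
    optionally weighting each sample by its majority size."""
    curves, _, _ = _fold_curves(preds, 0.5, weighted)
    summary = aggregate_roc_folds(curves)
    summary.weighting = "majority_size" if weighted else "none"
    return summary


def rejection_analysis(
    preds: list[EnsemblePredictions],
    thresholds: list[float],
    weighted: bool = False,
) -> list[RocSummary]:
    """Selective-prediction curves: for each majority-size threshold, reject
    less confident samples and re-aggregate the fold ROC on the rest."""
    out = []
    for tau in thresholds:
        if not 0.5 <= tau <= 1.0:
            raise ValueError(f"rejection threshold {tau} outside [0.5, 1]")
        curves, kept, total = _fold_curves(preds, tau, weighted)
        summary = aggregate_roc_folds(curves)
        summary.weighting = "majority_size" if weighted else "none"
        summary.rejection_threshold = tau
        summary.fraction_rejected = 1.0 - kept / total if total else 0.0
        out.append(summary)
    return out
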