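"""Cross-validation orchestration and bagged-ensemble uncertainty.

The experimental design: stratified k-fold cross-validation over the NSCLC
samples (non-NSCLC AD/SCC samples never enter a test fold; they join every
fold's training pool through the pan-tissue head). Within a fold, the
non-test samples are split 80/20 into training and validation, the training
set is bootstrapped once per ensemble member (with replacement, same size),
and one expression teacher is trained per fold. Each member is an
expression-aware genomic model trained on its bootstrap sample.

The ensemble prediction for a sample aggregates the members' lung-head
scores: the *majority class* is the subtype most members vote for (vote =
score >= 0.5), the *majority size* — the fraction of members in the
majority — is the prediction-uncertainty estimate (1 = unanimous, ~0.5 =
maximally uncertain), and the *aggregated score* is the mean score of
exactly the majority-voting members.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortDataset
from .models import (
    ModelConfig,
    ProfilingModel,
    TrainingResult,
    make_train_val_split,
    train_expression_aware_model,
    train_expression_model,
)

__all__ = [
    "CvPlan",
    "CvFold",
    "aggregate_scores",
    "EnsemblePredictions",
    "FoldEnsemble",
    "make_cv_plan",
    "bootstrap_training_sets",
    "train_ensemble",
    "predict_ensemble",
    "uncertainty_by_category",
    "run_ensemble_cv",
    "predictions_to_frame",
]

LUAD, LUSC = "LUAD", "LUSC"


@dataclass
class CvFold:
    test_ids: list[str]
    train_ids: list[str]
    val_ids: list[str]


@dataclass
class CvPlan:
    n_folds: int
    folds: list[CvFold]
    seed: int

    def check_no_leakage(self) -> None:
        for k, fold in enumerate(self.folds):
            test = set(fold.test_ids)
            if test & set(fold.train_ids) or test & set(fold.val_ids):
                raise AssertionError(f"fold {k}: test samples leak into train/val")
            if set(fold.train_ids) & set(fold.val_ids):
                raise AssertionError(f"fold {k}: train/val overlap")


def make_cv_plan(
    data: CohortDataset, n_folds: int = 10, seed: int = 0
) -> CvPlan:
    """Stratified k-fold plan over NSCLC samples.

    Test folds partition the NSCLC samples, stratified by subtype; the
    remaining NSCLC samples and *all* non-NSCLC samples are split 80/20
    (stratified) into training and validation per fold.
    """
    nsclc_idx = np.flatnonzero(data.is_nsclc)
    other_idx = np.flatnonzero(~data.is_nsclc)
    y_nsclc = data.labels[nsclc_idx]
    for c in (0.0, 1.0):
        if np.sum(y_nsclc == c) < n_folds:
            raise ValueError(
                f"class {int(c)} has fewer than n_folds={n_folds} NSCLC samples"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[CvFold] = []
    ids = np.asarray(data.sample_ids, dtype=object)
    for k, (rest, test) in enumerate(skf.split(nsclc_idx, y_nsclc)):
        rest_idx = nsclc_idx[rest]
        test_idx = nsclc_idx[test]
        tr, va = make_train_val_split(data.labels[rest_idx], 0.2, seed=seed + 17 * k + 1)
        train_idx = rest_idx[tr]
        val_idx = rest_idx[va]
        if len(other_idx):
            tr_o, va_o = make_train_val_split(
                data.labels[other_idx], 0.2, seed=seed + 17 * k + 2
            )
            train_idx = np.concatenate([train_idx, other_idx[tr_o]])
            val_idx = np.concatenate([val_idx, other_idx[va_o]])
        folds.append(
            CvFold(
                test_ids=list(ids[np.sort(test_idx)]),
                train_ids=list(ids[np.sort(train_idx)]),
                val_ids=list(ids[np.sort(val_idx)]),
            )
        )
    plan = CvPlan(n_folds=n_folds, folds=folds, seed=seed)
    plan.check_no_leakage()
    return plan


def bootstrap_training_sets(
    train_ids: list[str], n_models: int = 100, seed: int = 0
) -> list[list[str]]:
    """Bootstrap resamples of the training set: with replacement, each the
    same size as the training set, deterministic per seed."""
    if not train_ids:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    ids = np.asarray(train_ids, dtype=object)
    return [list(rng.choice(ids, size=len(ids), replace=True)) for _ in range(n_models)]


@dataclass
class FoldEnsemble:
    fold: int
    teacher: TrainingResult
    students: list[ProfilingModel]
    test_ids: list[str]
    train_ids: list[str]
    val_ids: list[str]


def train_ensemble(
    data: CohortDataset,
    plan: CvPlan,
    config: ModelConfig,
    n_models: int = 100,
) -> list[FoldEnsemble]:
    """Per fold: one expression teacher on the fold's training/validation
    split, then ``n_models`` expression-aware students, student *m* trained
    on bootstrap sample *m* with a seed derived from the base seed and *m*.
    The validation set is shared across a fold's models."""
    out: list[FoldEnsemble] = []
    for k, fold in enumerate(plan.folds):
        train_idx = data.sample_indices(fold.train_ids)
        val_idx = data.sample_indices(fold.val_ids)
        teacher_cfg = replace(config, seed=config.seed + 500_000 + k)
        teacher = train_expression_model(data, teacher_cfg, train_idx, val_idx)
        boots = bootstrap_training_sets(fold.train_ids, n_models, seed=config.seed + k)
        students = []
        for m, boot_ids in enumerate(boots):
            student_cfg = replace(config, seed=config.seed + (k + 1) * 100_000 + m)
            boot_idx = data.sample_indices(boot_ids)
            result = train_expression_aware_model(
                data, teacher.model, student_cfg, boot_idx, val_idx
            )
            students.append(result.model)
        out.append(
            FoldEnsemble(
                fold=k,
                teacher=teacher,
                students=students,
                test_ids=fold.test_ids,
                train_ids=fold.train_ids,
                val_ids=fold.val_ids,
            )
        )
    return out


@dataclass
class EnsemblePredictions:
    """Vectorized per-sample ensemble outputs for one set of samples."""

    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_models) lung-head outputs
    majority_class: np.ndarray  # "LUAD" / "LUSC"
    majority_size: np.ndarray  # fraction of members in the majority
    aggregated_score: np.ndarray  # mean score of the majority-voting members
    true_label: np.ndarray | None = None  # 1 = LUAD, 0 = LUSC
    fold: int | None = None

    @property
    def n_models(self) -> int:
        return self.scores.shape[1]

    @property
    def correct(self) -> np.ndarray:
        if self.true_label is None:
            raise ValueError("true labels unavailable")
        pred = (self.majority_class == LUAD).astype(float)
        return pred == self.true_label


def aggregate_scores(
    scores: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority vote over member scores.

    Votes use threshold 0.5 on the sigmoid output; an exact 50/50 tie is
    broken by the mean score against 0.5 (and to LUAD at exactly 0.5).
    Returns (is_luad, majority_size, aggregated_score), where the
    aggregated score is the mean score of exactly the majority-voting
    members.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, M = scores.shape
    votes = scores >= 0.5
    n_luad = votes.sum(axis=1)
    mean_score = scores.mean(axis=1)
    is_luad = np.where(n_luad * 2 == M, mean_score >= 0.5, n_luad * 2 > M)
    majority_size = np.maximum(n_luad, M - n_luad) / M
    sum_luad = (scores * votes).sum(axis=1)
    aggregated = np.where(
        is_luad,
        sum_luad / np.maximum(n_luad, 1),
        (scores.sum(axis=1) - sum_luad) / np.maximum(M - n_luad, 1),
    )
    return is_luad, majority_size, aggregated


def predict_ensemble(
    models: list[ProfilingModel],
    x: np.ndarray,
    sample_ids: list[str] | None = None,
    true_label: np.ndarray | None = None,
    fold: int | None = None,
) -> EnsemblePredictions:
    """Aggregate member lung-head scores into an ensemble prediction with a
    majority-size uncertainty; see :func:`aggregate_scores` for the rules."""
    if not models:
        raise ValueError("at least one model required")
    scores = np.column_stack([m.predict_lung(x) for m in models])
    n = scores.shape[0]
    is_luad, majority_size, aggregated = aggregate_scores(scores)
    return EnsemblePredictions(
        sample_ids=list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)],
        scores=scores,
        majority_class=np.where(is_luad, LUAD, LUSC).astype(object),
        majority_size=majority_size,
        aggregated_score=aggregated,
        true_label=None if true_label is None else np.asarray(true_label, dtype=float),
        fold=fold,
    )


def uncertainty_by_category(
    preds: EnsemblePredictions | list[EnsemblePredictions],
) -> dict[str, np.ndarray]:
    """Majority-size values grouped by confusion category (positive = LUAD)."""
    if isinstance(preds, EnsemblePredictions):
        preds = [preds]
    groups: dict[str, list[np.ndarray]] = {c: [] for c in ("TP", "FN", "TN", "FP")}
    for p in preds:
        if p.true_label is None:
            raise ValueError("true labels required")
        pred_luad = p.majority_class == LUAD
        truth = p.true_label == 1.0
        groups["TP"].append(p.majority_size[pred_luad & truth])
        groups["FN"].append(p.majority_size[~pred_luad & truth])
        groups["TN"].append(p.majority_size[~pred_luad & ~truth])
        groups["FP"].append(p.majority_size[pred_luad & ~truth])
    return {c: np.concatenate(v) if v else np.empty(0) for c, v in groups.items()}


def run_ensemble_cv(
    data: CohortDataset,
    config: ModelConfig,
    n_folds: int = 10,
    n_models: int = 100,
    seed: int | None = None,
) -> tuple[CvPlan, list[FoldEnsemble], list[EnsemblePredictions]]:
    """End-to-end cross-validated ensemble run; returns the plan, the
    trained per-fold ensembles, and per-fold test-set predictions."""
    if seed is not None:
        config = replace(config, seed=seed)
    plan = make_cv_plan(data, n_folds=n_folds, seed=config.seed)
    ensembles = train_ensemble(data, plan, config, n_models=n_models)
    preds = []
    for ens in ensembles:
        test_idx = data.sample_indices(ens.test_ids)
        preds.append(
            predict_ensemble(
                ens.students,
                data.mutation_matrix[test_idx].astype(float),
                sample_ids=ens.test_ids,
                true_label=data.labels[test_idx],
                fold=ens.fold,
            )
        )
    return plan, ensembles, preds


def predictions_to_frame(preds: list[EnsemblePredictions], with_scores: bool = False) -> pd.DataFrame:
    """Tidy predictions table (one row per test sample)."""
    rows = []
    for p in preds:
        df = pd.DataFrame(
            {
                "sample_id": p.sample_ids,
                "fold": p.fold,
                "true_label": p.true_label,
                "majority_class": p.majority_class,
                "majority_size": p.majority_size,
                "aggregated_score": p.aggregated_score,
            }
        )
        if with_scores:
            for m in range(p.n_models):
                df[f"score_{m:03d}"] = p.scores[:, m]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
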