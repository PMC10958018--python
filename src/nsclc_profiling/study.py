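"""Desk-scale reference study on a synthetic cohort.

Runs the full analysis end to end at a scale a single CPU handles in
minutes: a synthetic pan-cancer AD/SCC cohort (600 NSCLC + 600 non-lung
samples, 200 genes), a 5-fold cross-validated ensemble of 20
expression-aware genomic models per fold, per-fold expression teachers and
baseline genomic comparators, uncertainty-weighted and rejection ROC
analysis, driver-subgroup uncertainty comparison, and KernelSHAP
attribution of the ensemble prediction. The analysis scripts, the
acceptance script and the acceptance tests all drive this one entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortDataset
from .ensemble import (
    EnsemblePredictions,
    FoldEnsemble,
    predict_ensemble,
    run_ensemble_cv,
    uncertainty_by_category,
)
from .evaluation import RocSummary, aggregate_roc_folds, ensemble_roc, rejection_analysis, roc_curve
from .interpretation import (
    ShapResult,
    assign_driver_subgroups,
    ensemble_score_variance,
    explain_predictions,
)
from .models import ModelConfig, train_baseline_genomic
from .synthetic import default_config, generate_cohort

__all__ = ["StudyResult", "study_model_config", "run_study", "REJECTION_THRESHOLDS"]

REJECTION_THRESHOLDS = (0.5, 0.75, 0.95)


def study_model_config(seed: int = 0) -> ModelConfig:
    """Training configuration for the desk-scale study: the standard
    architecture and schedule, with the epoch budget capped at 120 (early
    stopping with patience 20 binds first in practice)."""
    return ModelConfig(max_epochs=120, seed=seed)


@dataclass
class StudyResult:
    cohort: CohortDataset
    preds: list[EnsemblePredictions]
    ensembles: list[FoldEnsemble] = field(repr=False, default=None)
    expression_auc: float = np.nan
    baseline_auc: float = np.nan
    ensemble_auc: float = np.nan
    ensemble_auc_sd: float = np.nan
    weighted_auc: float = np.nan
    rejection: dict[float, RocSummary] = field(default_factory=dict)
    mean_majority_correct: float = np.nan
    mean_majority_incorrect: float = np.nan
    uncertainty_by_category: dict[str, np.ndarray] = field(default_factory=dict)
    subgroup_mean_majority: dict[str, float] = field(default_factory=dict)
    shap_prediction: ShapResult | None = None
    driver_gene_names: list[str] = field(default_factory=list)
    error_auc_majority_size: float = np.nan
    error_auc_score_variance: float = np.nan


def _fold_model_auc(models_scores: list[tuple[np.ndarray, np.ndarray]]) -> float:
    curves = [roc_curve(s, y) for s, y in models_scores]
    return aggregate_roc_folds(curves).auc


def _uncertainty_error_auc(preds: list[EnsemblePredictions], confidence: list[np.ndarray]) -> float:
    """AUC of a confidence measure at separating correct from incorrect
    ensemble predictions (higher confidence should mean correct)."""
    conf = np.concatenate(confidence)
    correct = np.concatenate([p.correct for p in preds]).astype(float)
    if correct.min() == correct.max():
        return np.nan
    return roc_curve(conf, correct).auc


def run_study(
    seed: int = 1,
    n_folds: int = 5,
    n_models: int = 20,
    with_baseline: bool = True,
    with_shap: bool = True,
    shap_samples_per_fold: int = 4,
    shap_background: int = 12,
    shap_coalitions: int = 1024,
) -> StudyResult:
    """Run the reference study; deterministic given ``seed``."""
    sim = default_config(seed=seed)
    cohort = generate_cohort(sim)
    config = study_model_config(seed=seed)
    plan, ensembles, preds = run_ensemble_cv(
        cohort, config, n_folds=n_folds, n_models=n_models
    )
    result = StudyResult(cohort=cohort, preds=preds, ensembles=ensembles)
    result.driver_gene_names = [
        cohort.gene_ids[d.gene_index] for d in sim.driver_spec
    ]

    # fold-aggregated ROC of the per-fold expression teachers on NSCLC tests
    teacher_scores = []
    baseline_scores = []
    for ens in ensembles:
        test_idx = cohort.sample_indices(ens.test_ids)
        y = cohort.labels[test_idx]
        teacher_scores.append(
            (ens.teacher.model.predict_lung(cohort.expression_matrix[test_idx]), y)
        )
        if with_baseline:
            base_cfg = replace(config, seed=config.seed + 900_000 + ens.fold)
            base = train_baseline_genomic(
                cohort,
                base_cfg,
                cohort.sample_indices(ens.train_ids),
                cohort.sample_indices(ens.val_ids),
            )
            baseline_scores.append(
                (base.model.predict_lung(cohort.mutation_matrix[test_idx].astype(float)), y)
            )
    result.expression_auc = _fold_model_auc(teacher_scores)
    if with_baseline:
        result.baseline_auc = _fold_model_auc(baseline_scores)

    unweighted = ensemble_roc(preds, weighted=False)
    result.ensemble_auc = unweighted.auc
    result.ensemble_auc_sd = unweighted.auc_sd
    result.weighted_auc = ensemble_roc(preds, weighted=True).auc
    result.rejection = {
        s.rejection_threshold: s
        for s in rejection_analysis(preds, list(REJECTION_THRESHOLDS))
    }

    cats = uncertainty_by_category(preds)
    result.uncertainty_by_category = cats
    correct_u = np.concatenate([cats["TP"], cats["TN"]])
    incorrect_u = np.concatenate([cats["FN"], cats["FP"]])
    result.mean_majority_correct = float(correct_u.mean()) if correct_u.size else np.nan
    result.mean_majority_incorrect = (
        float(incorrect_u.mean()) if incorrect_u.size else np.nan
    )

    # majority size vs. prediction variance as error-detection signals
    result.error_auc_majority_size = _uncertainty_error_auc(
        preds, [p.majority_size for p in preds]
    )
    result.error_auc_score_variance = _uncertainty_error_auc(
        preds, [-ensemble_score_variance(p) for p in preds]
    )

    # driver-mutation subgroups over the NSCLC test samples
    subgroups = assign_driver_subgroups(cohort)
    sub_by_id = dict(zip(cohort.sample_ids, subgroups))
    all_u = np.concatenate([p.majority_size for p in preds])
    all_sub = np.concatenate(
        [[sub_by_id[s] for s in p.sample_ids] for p in preds]
    )
    for grp in ("LUAD-driver", "LUSC-driver", "mixed", "neither"):
        mask = all_sub == grp
        result.subgroup_mean_majority[grp] = (
            float(all_u[mask].mean()) if mask.any() else np.nan
        )

    if with_shap:
        result.shap_prediction = explain_predictions(
            ensembles,
            cohort,
            background_size=shap_background,
            n_coalitions=shap_coalitions,
            seed=seed,
            max_samples_per_fold=shap_samples_per_fold,
        )
    return result
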