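"""Attribution and manifold analysis of the ensemble.

KernelSHAP estimates Shapley values of binary gene-mutation features for
two black-box targets: the ensemble's aggregated prediction score (LUAD
axis, 1 = LUAD) and its majority-size uncertainty (1 = most confident,
0.5 = most uncertain). The estimator fits a weighted linear surrogate over
feature coalitions with the Shapley kernel; masked-out features are imputed
from a background sample, and the solve is constrained so attributions sum
exactly to f(x) minus the background expectation (local accuracy). When the
coalition budget covers all 2^M - 2 non-trivial coalitions the estimates
are the exact Shapley values of the background-imputed value function.

Also here: UMAP comparison of expression vs. genomic latent manifolds,
driver-gene subgroup assignment (LUAD drivers BRAF/EGFR/KRAS/STK11 vs.
LUSC drivers CDKN2A/NFE2L2/PIK3CA/PTEN, TP53 excluded as recurrently
mutated in both), single-gene comparator rules, and the prediction-variance
alternative uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np

from .cohort import CohortDataset
from .ensemble import EnsemblePredictions, FoldEnsemble, predict_ensemble

__all__ = [
    "ShapResult",
    "kernel_shap",
    "explain_predictions",
    "explain_uncertainty",
    "umap_compare",
    "LUAD_DRIVERS",
    "LUSC_DRIVERS",
    "assign_driver_subgroups",
    "univariable_model",
    "ensemble_score_variance",
]

LUAD_DRIVERS = frozenset({"BRAF", "EGFR", "KRAS", "STK11"})
LUSC_DRIVERS = frozenset({"CDKN2A", "NFE2L2", "PIK3CA", "PTEN"})


@dataclass
class ShapResult:
    """Per-sample per-feature attributions against a baseline expectation."""

    target_function: str  # "prediction" or "uncertainty"
    baseline: float  # E[f(x)] over the background
    attributions: np.ndarray  # (n_samples, n_features)
    fx: np.ndarray  # f at each explained sample
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None

    @property
    def global_importance(self) -> np.ndarray:
        """Mean absolute attribution per feature across explained samples."""
        return np.abs(self.attributions).mean(axis=0)

    def top_features(self, k: int = 20) -> list[tuple[str, float]]:
        imp = self.global_importance
        order = np.argsort(imp)[::-1][:k]
        names = self.feature_names or [f"f{j}" for j in range(len(imp))]
        return [(names[j], float(imp[j])) for j in order]

    def merge(self, other: "ShapResult") -> "ShapResult":
        """Concatenate attributions from another fold (baseline averaged,
        weighted by explained-sample counts)."""
        if self.target_function != other.target_function:
            raise ValueError("cannot merge attributions for different targets")
        n1, n2 = len(self.fx), len(other.fx)
        return ShapResult(
            target_function=self.target_function,
            baseline=(self.baseline * n1 + other.baseline * n2) / (n1 + n2),
            attributions=np.vstack([self.attributions, other.attributions]),
            fx=np.concatenate([self.fx, other.fx]),
            feature_names=self.feature_names,
            sample_ids=(self.sample_ids or []) + (other.sample_ids or []),
        )


def _shapley_kernel_weights(M: int, sizes: np.ndarray) -> np.ndarray:
    return np.asarray(
        [(M - 1) / (comb(M, int(s)) * s * (M - s)) for s in sizes], dtype=float
    )


def _coalition_masks(
    M: int, n_coalitions: int | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coalition 0/1 masks and their Shapley-kernel weights.

    Enumerates all 2^M - 2 non-trivial coalitions when the budget allows
    (yielding exact Shapley values); otherwise samples coalition sizes from
    the kernel distribution and subsets uniformly within a size.
    """
    total = 2**M - 2
    if n_coalitions is None or n_coalitions >= total:
        masks = np.zeros((total, M), dtype=np.int8)
        for i in range(1, 2**M - 1):
            masks[i - 1] = [(i >> j) & 1 for j in range(M)]
        weights = _shapley_kernel_weights(M, masks.sum(axis=1))
        return masks, weights
    sizes = np.arange(1, M)
    p_size = (M - 1) / (sizes * (M - sizes))
    p_size /= p_size.sum()
    drawn = rng.choice(sizes, size=n_coalitions, p=p_size)
    masks = np.zeros((n_coalitions, M), dtype=np.int8)
    for i, s in enumerate(drawn):
        masks[i, rng.choice(M, size=int(s), replace=False)] = 1
    # sampled coalitions already follow the kernel size distribution;
    # uniform weights avoid double counting
    return masks, np.ones(n_coalitions)


def kernel_shap(
    f: Callable[[np.ndarray], np.ndarray],
    X_explain: np.ndarray,
    X_background: np.ndarray,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> ShapResult:
    """KernelSHAP attributions of ``f`` for each row of ``X_explain``.

    ``f`` maps a 2-D array of feature rows to a 1-D array of real outputs.
    For every coalition, masked-out features are imputed from each
    background row in turn and f is averaged over the background. The
    constrained weighted-least-squares solve enforces local accuracy:
    attributions sum to f(x) - E[f] exactly.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    if X_background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    n, M = X_explain.shape
    rng = np.random.default_rng(seed)
    baseline = float(np.mean(f(X_background)))
    fx = np.asarray(f(X_explain), dtype=float)

    masks, weights = _coalition_masks(M, n_coalitions, rng)
    C, B = masks.shape[0], X_background.shape[0]
    sw = np.sqrt(weights)

    attributions = np.zeros((n, M))
    for i in range(n):
        x = X_explain[i]
        # (C*B, M): coalition-present features from x, absent from background
        tiled_bg = np.tile(X_background, (C, 1))
        masked = np.repeat(masks, B, axis=0) * x + (1 - np.repeat(masks, B, axis=0)) * tiled_bg
        v = f(masked).reshape(C, B).mean(axis=1)

        delta = fx[i] - baseline
        if C == 0:  # single feature: the sum constraint determines phi
            attributions[i, -1] = delta
            continue
        if np.allclose(v, v[0]) and abs(delta) < 1e-12:
            continue  # constant f: all-zero attributions
        # eliminate phi_M via the sum constraint, then WLS
        y = v - baseline - masks[:, -1] * delta
        A = masks[:, :-1] - masks[:, -1][:, None]
        phi_rest, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        attributions[i, :-1] = phi_rest
        attributions[i, -1] = delta - phi_rest.sum()
    return ShapResult(
        target_function="custom",
        baseline=baseline,
        attributions=attributions,
        fx=fx,
    )


def _class_balanced_background(
    data: CohortDataset, ids: list[str], size: int, rng: np.random.Generator
) -> np.ndarray:
    idx = data.sample_indices(ids)
    y = data.labels[idx]
    per_class = size // 2
    rows = []
    for c in (1.0, 0.0):
        pool = idx[y == c]
        take = min(per_class, len(pool))
        rows.append(rng.choice(pool, size=take, replace=False))
    return data.mutation_matrix[np.concatenate(rows)].astype(float)


def _explain_target(
    ensembles: list[FoldEnsemble],
    data: CohortDataset,
    target: str,
    background_size: int,
    n_coalitions: int | None,
    seed: int,
    max_samples_per_fold: int | None,
) -> ShapResult:
    merged: ShapResult | None = None
    for ens in ensembles:
        rng = np.random.default_rng(seed + ens.fold)
        test_idx = data.sample_indices(ens.test_ids)
        if max_samples_per_fold is not None and len(test_idx) > max_samples_per_fold:
            test_idx = rng.choice(test_idx, size=max_samples_per_fold, replace=False)
        background = _class_balanced_background(
            data, ens.train_ids, background_size, rng
        )
        students = ens.students

        def f(xs: np.ndarray) -> np.ndarray:
            preds = predict_ensemble(students, xs)
            if target == "prediction":
                return preds.aggregated_score
            return preds.majority_size

        result = kernel_shap(
            f,
            data.mutation_matrix[test_idx].astype(float),
            background,
            n_coalitions=n_coalitions,
            seed=seed + 1000 + ens.fold,
        )
        result.target_function = target
        result.feature_names = list(data.gene_ids)
        result.sample_ids = [data.sample_ids[i] for i in test_idx]
        merged = result if merged is None else merged.merge(result)
    return merged


def explain_predictions(
    ensembles: list[FoldEnsemble],
    data: CohortDataset,
    background_size: int = 50,
    n_coalitions: int | None = None,
    seed: int = 0,
    max_samples_per_fold: int | None = None,
) -> ShapResult:
    """Gene attributions for the ensemble's aggregated prediction score,
    estimated separately per testing fold and merged. ``n_coalitions``
    defaults to 2*n_genes + 2048."""
    if n_coalitions is None:
        n_coalitions = 2 * data.n_genes + 2048
    return _explain_target(
        ensembles, data, "prediction", background_size, n_coalitions, seed,
        max_samples_per_fold,
    )


def explain_uncertainty(
    ensembles: list[FoldEnsemble],
    data: CohortDataset,
    background_size: int = 50,
    n_coalitions: int | None = None,
    seed: int = 0,
    max_samples_per_fold: int | None = None,
) -> ShapResult:
    """Gene attributions for the majority-size uncertainty (positive values
    increase prediction confidence)."""
    if n_coalitions is None:
        n_coalitions = 2 * data.n_genes + 2048
    return _explain_target(
        ensembles, data, "uncertainty", background_size, n_coalitions, seed,
        max_samples_per_fold,
    )


def umap_compare(
    expression_latents: np.ndarray,
    genomic_latents: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit UMAP on expression latents, transform genomic latents through it.

    Returns (expression embedding, genomic embedding). Passing the fitted
    matrix itself as ``genomic_latents`` returns the fitted embedding (the
    fit-transform consistency contract).
    """
    expression_latents = np.asarray(expression_latents, dtype=float)
    genomic_latents = np.asarray(genomic_latents, dtype=float)
    if expression_latents.shape[0] < n_neighbors:
        raise ValueError(
            f"need at least n_neighbors={n_neighbors} samples, "
            f"got {expression_latents.shape[0]}"
        )
    import umap  # deferred: slow import

    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    emb_expr = reducer.fit_transform(expression_latents)
    if np.array_equal(expression_latents, genomic_latents):
        emb_gen = emb_expr.copy()
    else:
        emb_gen = reducer.transform(genomic_latents)
    return emb_expr, emb_gen


def assign_driver_subgroups(
    data: CohortDataset,
    luad_drivers: frozenset[str] = LUAD_DRIVERS,
    lusc_drivers: frozenset[str] = LUSC_DRIVERS,
) -> np.ndarray:
    """Per-sample subgroup from driver mutations: 'mixed' if the sample
    carries >= 1 mutated driver of each subtype, 'LUAD-driver'/'LUSC-driver'
    for exactly one side, 'neither' otherwise. Missing driver genes are
    treated as unmutated (with a warning)."""
    def side_mask(drivers: frozenset[str]) -> np.ndarray:
        cols = []
        for g in sorted(drivers):
            if g in data.gene_ids:
                cols.append(data.gene_index(g))
            else:
                warnings.warn(f"driver gene {g} absent from cohort; treated unmutated",
                              stacklevel=2)
        if not cols:
            return np.zeros(data.n_samples, dtype=bool)
        return data.mutation_matrix[:, cols].any(axis=1)

    has_luad = side_mask(luad_drivers)
    has_lusc = side_mask(lusc_drivers)
    labels = np.full(data.n_samples, "neither", dtype=object)
    labels[has_luad & ~has_lusc] = "LUAD-driver"
    labels[~has_luad & has_lusc] = "LUSC-driver"
    labels[has_luad & has_lusc] = "mixed"
    return labels


def univariable_model(
    data: CohortDataset,
    gene: str,
    associated_subtype: str,
    ensemble_preds: Sequence[EnsemblePredictions] | None = None,
) -> dict:
    """Single-gene comparator: mutated -> the associated subtype, otherwise
    the other subtype. Reports accuracy on the subgroup of samples mutated
    in the gene, next to the ensemble's accuracy on the same subgroup."""
    if associated_subtype not in ("LUAD", "LUSC"):
        raise ValueError("associated_subtype must be LUAD or LUSC")
    mutated = data.mutation_matrix[:, data.gene_index(gene)] == 1
    other = "LUSC" if associated_subtype == "LUAD" else "LUAD"
    predicted = np.where(mutated, associated_subtype, other).astype(object)
    truth = np.where(data.labels == 1.0, "LUAD", "LUSC").astype(object)

    sub = mutated & data.is_nsclc
    out = {
        "predicted": predicted,
        "subgroup_size": int(sub.sum()),
        "univariable_accuracy": float((predicted[sub] == truth[sub]).mean())
        if sub.any()
        else np.nan,
    }
    if ensemble_preds is not None:
        agree = []
        sub_ids = {data.sample_ids[i] for i in np.flatnonzero(sub)}
        for p in ensemble_preds:
            in_sub = np.asarray([s in sub_ids for s in p.sample_ids])
            if in_sub.any():
                pred_luad = (p.majority_class[in_sub] == "LUAD").astype(float)
                agree.append(pred_luad == p.true_label[in_sub])
        out["ensemble_accuracy"] = (
            float(np.concatenate(agree).mean()) if agree else np.nan
        )
    return out


def ensemble_score_variance(preds: EnsemblePredictions) -> np.ndarray:
    """Sample variance (ddof=1) of per-member scores — the alternative
    prediction-uncertainty estimate the majority size is compared against."""
    if preds.n_models < 2:
        raise ValueError("score variance requires at least 2 models")
    return preds.scores.var(axis=1, ddof=1)
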