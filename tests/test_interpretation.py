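"""Attribution correctness (exact Shapley oracle), driver subgroups,
comparator rules, manifold comparison."""

import itertools
import math

import numpy as np
import pytest

from nsclc_profiling.cohort import AD, SCC
from nsclc_profiling.ensemble import EnsemblePredictions
from nsclc_profiling.interpretation import (
    LUAD_DRIVERS,
    LUSC_DRIVERS,
    assign_driver_subgroups,
    ensemble_score_variance,
    kernel_shap,
    umap_compare,
    univariable_model,
)
from nsclc_profiling.synthetic import default_config, generate_cohort


def exact_shapley(f, x, background):
    """Exhaustive Shapley values of the background-imputed value function."""
    M = len(x)
    v = {}
    for size in range(M + 1):
        for S in itertools.combinations(range(M), size):
            masked = np.tile(background, (1, 1)).copy()
            masked = background.copy()
            for j in S:
                masked[:, j] = x[j]
            v[S] = float(np.mean(f(masked)))
    phi = np.zeros(M)
    for j in range(M):
        for size in range(M):
            for S in itertools.combinations([k for k in range(M) if k != j], size):
                wgt = math.factorial(size) * math.factorial(M - size - 1) / math.factorial(M)
                phi[j] += wgt * (v[tuple(sorted(S + (j,)))] - v[S])
    return phi


class TestKernelShap:
    def test_constant_function_gives_zero_attributions(self):
        f = lambda X: np.full(len(X), 0.7)
        res = kernel_shap(f, np.ones((3, 4)), np.zeros((2, 4)), seed=0)
        np.testing.assert_allclose(res.attributions, 0.0)
        assert res.baseline == pytest.approx(0.7)

    def test_single_feature_closed_form(self):
        f = lambda X: X[:, 0]
        res = kernel_shap(f, np.array([[1.0]]), np.zeros((3, 1)), seed=0)
        assert res.attributions[0, 0] == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_exact_shapley(self):
        """5-feature nonlinear f with interactions, vs the exact oracle."""
        rng = np.random.default_rng(0)
        background = rng.integers(0, 2, (4, 5)).astype(float)

        def f(X):
            return X[:, 0] + 2.0 * X[:, 1] * X[:, 2] - 1.5 * X[:, 3] + 0.5 * X[:, 4] * X[:, 0]

        X_explain = np.array([[1, 1, 0, 1, 1], [0, 1, 1, 0, 0]], dtype=float)
        res = kernel_shap(f, X_explain, background, n_coalitions=None, seed=0)
        for i in range(len(X_explain)):
            expected = exact_shapley(f, X_explain[i], background)
            np.testing.assert_allclose(res.attributions[i], expected, atol=1e-6)

    def test_local_accuracy_with_sampled_coalitions(self):
        rng = np.random.default_rng(1)
        M = 30
        w = rng.standard_normal(M)
        f = lambda X: 1 / (1 + np.exp(-(X @ w)))
        X_explain = rng.integers(0, 2, (3, M)).astype(float)
        background = rng.integers(0, 2, (8, M)).astype(float)
        res = kernel_shap(f, X_explain, background, n_coalitions=400, seed=0)
        np.testing.assert_allclose(
            res.attributions.sum(axis=1), res.fx - res.baseline, atol=1e-8
        )

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            kernel_shap(lambda X: X[:, 0], np.ones((1, 2)), np.empty((0, 2)))


class TestDriverSubgroups:
    def _cohort_from_drivers(self, table):
        genes = sorted(LUAD_DRIVERS) + sorted(LUSC_DRIVERS)
        n = len(table)
        return _cohort(np.asarray(table, dtype=np.uint8), genes, n)

    def test_kras_plus_pten_is_mixed(self):
        genes = sorted(LUAD_DRIVERS) + sorted(LUSC_DRIVERS)
        row = np.zeros((1, 8), dtype=np.uint8)
        row[0, genes.index("KRAS")] = 1
        row[0, genes.index("PTEN")] = 1
        labels = assign_driver_subgroups(self._cohort_from_drivers(row))
        assert labels[0] == "mixed"

    def test_all_wild_type_is_neither(self):
        labels = assign_driver_subgroups(self._cohort_from_drivers(np.zeros((2, 8))))
        assert (labels == "neither").all()

    def test_matches_brute_force_set_logic(self):
        rng = np.random.default_rng(3)
        table = rng.integers(0, 2, (50, 8)).astype(np.uint8)
        data = self._cohort_from_drivers(table)
        labels = assign_driver_subgroups(data)
        genes = data.gene_ids
        for i in range(50):
            mutated = {g for j, g in enumerate(genes) if table[i, j]}
            has_l = bool(mutated & LUAD_DRIVERS)
            has_s = bool(mutated & LUSC_DRIVERS)
            expected = (
                "mixed" if has_l and has_s
                else "LUAD-driver" if has_l
                else "LUSC-driver" if has_s
                else "neither"
            )
            assert labels[i] == expected

    def test_missing_driver_gene_warns(self):
        data = _cohort(np.zeros((2, 1), dtype=np.uint8), ["KRAS"], 2)
        with pytest.warns(UserWarning, match="absent"):
            labels = assign_driver_subgroups(data)
        assert (labels == "neither").all()


def _cohort(mut, genes, n):
    from nsclc_profiling.cohort import CohortDataset

    return CohortDataset(
        mutation_matrix=mut,
        expression_matrix=np.zeros_like(mut, dtype=float),
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=list(genes),
        histology=np.asarray([AD if i % 2 == 0 else SCC for i in range(n)], dtype=object),
        tissue=np.asarray(["lung"] * n, dtype=object),
        is_lung=np.ones(n, dtype=bool),
    )


class TestUnivariable:
    def test_mutated_sample_gets_associated_subtype(self):
        data = _cohort(np.array([[1], [0]], dtype=np.uint8), ["KRAS"], 2)
        out = univariable_model(data, "KRAS", "LUAD")
        assert out["predicted"].tolist() == ["LUAD", "LUSC"]

    def test_gene_absent_everywhere_predicts_other_subtype(self):
        data = _cohort(np.zeros((3, 1), dtype=np.uint8), ["KRAS"], 3)
        out = univariable_model(data, "KRAS", "LUAD")
        assert (out["predicted"] == "LUSC").all()
        assert np.isnan(out["univariable_accuracy"])

    def test_toy_table_accuracy_matches_hand_count(self):
        # histology alternates AD, SCC, AD, SCC, AD, SCC (AD = LUAD here)
        mut = np.array([[1], [1], [1], [0], [0], [0]], dtype=np.uint8)
        data = _cohort(mut, ["KRAS"], 6)
        out = univariable_model(data, "KRAS", "LUAD")
        # mutated subgroup = samples 0,1,2 with truth LUAD, LUSC, LUAD
        assert out["subgroup_size"] == 3
        assert out["univariable_accuracy"] == pytest.approx(2 / 3)

    def test_ensemble_comparison_on_subgroup(self):
        mut = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        data = _cohort(mut, ["KRAS"], 4)
        preds = EnsemblePredictions(
            sample_ids=["s0", "s1"],
            scores=np.array([[0.9, 0.8], [0.9, 0.7]]),
            majority_class=np.array(["LUAD", "LUAD"], dtype=object),
            majority_size=np.array([1.0, 1.0]),
            aggregated_score=np.array([0.85, 0.8]),
            true_label=np.array([1.0, 0.0]),
        )
        out = univariable_model(data, "KRAS", "LUAD", [preds])
        assert out["ensemble_accuracy"] == pytest.approx(0.5)


class TestScoreVariance:
    def _preds(self, scores):
        scores = np.asarray(scores, dtype=float)
        return EnsemblePredictions(
            sample_ids=[str(i) for i in range(len(scores))],
            scores=scores,
            majority_class=np.asarray(["LUAD"] * len(scores), dtype=object),
            majority_size=np.ones(len(scores)),
            aggregated_score=scores.mean(axis=1),
        )

    def test_identical_scores_zero_variance(self):
        assert ensemble_score_variance(self._preds([[0.7, 0.7, 0.7]]))[0] == pytest.approx(
            0.0, abs=1e-15
        )

    def test_two_model_closed_form(self):
        assert ensemble_score_variance(self._preds([[0.0, 1.0]]))[0] == pytest.approx(0.5)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.random((10, 7))
        got = ensemble_score_variance(self._preds(scores))
        for i in range(10):
            mean = scores[i].sum() / 7
            expected = ((scores[i] - mean) ** 2).sum() / 6
            assert got[i] == pytest.approx(expected, rel=1e-12)

    def test_single_model_errors(self):
        with pytest.raises(ValueError):
            ensemble_score_variance(self._preds([[0.5]]))


class TestUmap:
    @pytest.fixture(scope="class")
    def latents(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((40, 8)) + 4.0
        b = rng.standard_normal((40, 8)) - 4.0
        expr = np.vstack([a, b])
        genomic = expr + 0.3 * rng.standard_normal(expr.shape)
        labels = np.array([0] * 40 + [1] * 40)
        return expr, genomic, labels

    def test_fit_transform_consistency(self, latents):
        expr, _, _ = latents
        emb_expr, emb_same = umap_compare(expr, expr.copy(), seed=0)
        np.testing.assert_array_equal(emb_expr, emb_same)

    def test_separation_preserved(self, latents):
        from sklearn.metrics import silhouette_score

        expr, genomic, labels = latents
        emb_expr, emb_gen = umap_compare(expr, genomic, seed=0)
        assert silhouette_score(emb_expr, labels) > 0
        assert silhouette_score(emb_gen, labels) > 0

    def test_fixed_seed_repeats(self, latents):
        expr, genomic, _ = latents
        a = umap_compare(expr, genomic, seed=1)
        b = umap_compare(expr, genomic, seed=1)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_samples_errors(self, latents):
        expr, genomic, _ = latents
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_compare(expr[:5], genomic[:5], n_neighbors=15)


def test_driver_subgroup_rate_at_least_mixed_fraction():
    cfg = default_config(seed=4, n_samples_per_group=100)
    data = generate_cohort(cfg)
    labels = assign_driver_subgroups(data)
    assert (labels == "mixed").mean() >= cfg.mixed_driver_fraction
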