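import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmesig.cluster import (
    GapCurve,
    SubtypeModel,
    align_cluster_labels,
    assign_to_reference,
    discover_subtypes,
    gap_statistic,
    kmeans_cluster,
    pairwise_within_dispersion,
    select_k,
    within_dispersion,
    zscore_genes,
)
from tmesig.io import ExpressionMatrix
from tmesig.simulate import simulate_bulk_cohort

from conftest import make_matrix


def _blob_matrix(seed=0, n=40, p=5):
    rng = np.random.default_rng(seed)
    return make_matrix(rng.normal(0, 1, size=(p, n)))


def _planted_cohort(seed=0, n=120):
    mx, _, truth = simulate_bulk_cohort(
        n_samples=n, n_genes=300, seed=seed
    )
    genes = sorted(set().union(*truth.signature_genes.values()))
    return zscore_genes(mx, genes), truth


class TestZscore:
    def test_row_means_zero_sds_one(self, random_matrix):
        z = zscore_genes(random_matrix, random_matrix.gene_ids)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_idempotent(self, random_matrix):
        z1 = zscore_genes(random_matrix, random_matrix.gene_ids)
        z2 = zscore_genes(z1, z1.gene_ids)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_constant_gene_dropped_with_warning(self):
        mx = make_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "var"])
        with pytest.warns(UserWarning, match="flat"):
            z = zscore_genes(mx, ["flat", "var"])
        assert z.gene_ids == ["var"]

    def test_missing_gene_listed_in_error(self, random_matrix):
        with pytest.raises(KeyError, match="nope"):
            zscore_genes(random_matrix, ["nope"])


class TestKMeans:
    def test_k_one_single_cluster_total_dispersion(self):
        mx = _blob_matrix()
        fit = kmeans_cluster(mx, 1, seed=0)
        assert set(fit.labels) == {1}
        X = mx.values.T
        np.testing.assert_allclose(fit.w_k, ((X - X.mean(0)) ** 2).sum(), rtol=1e-9)

    def test_k_equals_n_zero_dispersion(self):
        mx = _blob_matrix(n=8)
        fit = kmeans_cluster(mx, 8, n_init=5, seed=0)
        assert fit.w_k == pytest.approx(0.0, abs=1e-12)

    def test_dispersion_identity_pairwise_vs_sse(self):
        mx = _blob_matrix(seed=2, n=30)
        fit = kmeans_cluster(mx, 3, n_init=5, seed=1)
        X = mx.values.T
        assert within_dispersion(X, fit.labels) == pytest.approx(
            pairwise_within_dispersion(X, fit.labels), rel=1e-9
        )

    def test_sample_order_invariance(self):
        mx = _blob_matrix(seed=3, n=30)
        fit = kmeans_cluster(mx, 3, n_init=5, seed=5)
        perm = np.random.default_rng(0).permutation(mx.n_samples)
        mx_p = ExpressionMatrix(mx.data.iloc[:, perm])
        fit_p = kmeans_cluster(mx_p, 3, n_init=5, seed=5)
        assert list(fit_p.labels) == [fit.labels[i] for i in perm]

    def test_recovers_planted_subtypes(self):
        z, truth = _planted_cohort(seed=4)
        fit = kmeans_cluster(z, 6, n_init=10, seed=4)
        assert adjusted_rand_score(truth.subtype_labels.to_numpy(), fit.labels) >= 0.9

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(_blob_matrix(n=5), 6)


class TestGapStatistic:
    def test_sample_permutation_leaves_gap_unchanged(self):
        mx = _blob_matrix(seed=6, n=25)
        curve = gap_statistic(mx, k_range=(2, 3), b_refs=10, n_init=5, seed=2)
        perm = np.random.default_rng(1).permutation(mx.n_samples)
        curve_p = gap_statistic(
            ExpressionMatrix(mx.data.iloc[:, perm]),
            k_range=(2, 3), b_refs=10, n_init=5, seed=2,
        )
        np.testing.assert_allclose(curve.gap, curve_p.gap, atol=1e-9)

    def test_log_wk_non_increasing_in_k(self):
        z, _ = _planted_cohort(seed=7)
        curve = gap_statistic(z, k_range=(2, 3, 4, 5), b_refs=10, n_init=10, seed=3)
        assert np.all(np.diff(curve.log_wk) <= 1e-9)

    def test_single_blob_selects_small_k(self):
        hits = 0
        for seed in range(5):
            mx = _blob_matrix(seed=seed, n=60, p=4)
            curve = gap_statistic(mx, k_range=(2, 3, 4, 5), b_refs=10, n_init=5, seed=seed)
            hits += select_k(curve, "first_se_max") <= 3
        assert hits >= 4

    def test_b_refs_floor_enforced(self):
        with pytest.raises(ValueError, match="b_refs"):
            gap_statistic(_blob_matrix(), k_range=(2, 3), b_refs=5)


class TestSelectK:
    def test_global_max_and_tie_break(self):
        curve = GapCurve([3, 4, 5], [0.1, 0.5, 0.3], [0.01] * 3, [1, 0.8, 0.6], 10)
        assert select_k(curve) == 4
        tie = GapCurve([3, 4, 5], [0.5, 0.5, 0.3], [0.01] * 3, [1, 0.8, 0.6], 10)
        assert select_k(tie) == 3

    def test_first_se_max_monotone_curve_returns_largest_k(self):
        curve = GapCurve([3, 4, 5], [0.1, 0.2, 0.4], [1e-6] * 3, [1, 0.8, 0.6], 10)
        assert select_k(curve, "first_se_max") == 5

    def test_empty_curve_rejected(self):
        curve = GapCurve([], [], [], [], 10)
        with pytest.raises(ValueError):
            select_k(curve)


class TestAlignLabels:
    def test_identity_and_swap(self):
        a = [1, 1, 2, 2]
        assert align_cluster_labels(a, a) == {1: 1, 2: 2}
        assert align_cluster_labels(a, [2, 2, 1, 1]) == {2: 1, 1: 2}

    def test_alignment_never_decreases_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(1, 4, 50)
            b = rng.integers(1, 4, 50)
            mapping = align_cluster_labels(a, b)
            before = np.mean(a == b)
            after = np.mean(a == np.array([mapping.get(x, x) for x in b]))
            assert after >= before


class TestAssignToReference:
    def _model(self, seed=8):
        z, truth = _planted_cohort(seed=seed)
        fit = kmeans_cluster(z, 6, n_init=10, seed=seed)
        return (
            SubtypeModel(
                k=6, signature_genes=z.gene_ids, centroids=fit.centroids,
                labels=pd.Series(fit.labels, index=z.sample_ids),
                gap_curve=None, seed=seed,
            ),
            truth,
        )

    def test_sample_equal_to_centroid_gets_its_label(self):
        model, _ = self._model()
        new = ExpressionMatrix(
            pd.DataFrame(
                model.centroids.to_numpy().T,
                index=model.signature_genes,
                columns=[f"c{i}" for i in range(model.k)],
            )
        )
        labels = assign_to_reference(new, model, rescale=False)
        assert list(labels) == list(range(1, model.k + 1))

    def test_second_cohort_agrees_with_planted_labels(self):
        model, _ = self._model(seed=8)
        mx2, _, truth2 = simulate_bulk_cohort(n_samples=120, n_genes=300, seed=9)
        labels = assign_to_reference(mx2, model)
        mapping = align_cluster_labels(truth2.subtype_labels.to_numpy(), labels.to_numpy())
        agree = np.mean(
            truth2.subtype_labels.to_numpy()
            == np.array([mapping.get(x, x) for x in labels])
        )
        assert agree >= 0.85

    def test_constant_sample_flagged_by_name(self):
        model, _ = self._model()
        data = pd.DataFrame(
            np.zeros((len(model.signature_genes), 2)),
            index=model.signature_genes, columns=["flat1", "flat2"],
        )
        data["flat2"] = np.arange(len(data))
        with pytest.raises(ValueError, match="flat1"):
            assign_to_reference(ExpressionMatrix(data), model, rescale=False)

    def test_low_coverage_rejected(self):
        model, _ = self._model()
        keep = model.signature_genes[: len(model.signature_genes) // 2]
        data = pd.DataFrame(
            np.random.default_rng(0).normal(size=(len(keep), 4)), index=keep
        )
        with pytest.raises(ValueError, match="covers only"):
            assign_to_reference(ExpressionMatrix(data), model)


class TestDiscoverAndSerialize:
    def test_model_json_round_trip(self, tmp_path):
        z, _ = _planted_cohort(seed=10, n=60)
        model = discover_subtypes(
            z, z.gene_ids, k_range=(5, 6, 7), b_refs=10, n_init=5,
            rule="first_se_max", seed=10,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SubtypeModel.from_json(path)
        assert back.k == model.k
        assert back.signature_genes == model.signature_genes
        np.testing.assert_allclose(
            back.centroids.to_numpy(), model.centroids.to_numpy(), atol=1e-12
        )
        assert list(back.labels) == list(model.labels)
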