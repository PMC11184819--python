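"""Cluster-quality metrics, GSEA, and performance-table transforms."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

import scperf as sp
from scperf.metrics import PURITY_METRICS

from conftest import toy_counts


def _random_instance(rng, n=None, d=None, k=None):
    n = n or int(rng.integers(20, 80))
    d = d or int(rng.integers(2, 8))
    k = k or int(rng.integers(2, 5))
    X = rng.normal(size=(n, d))
    labels = rng.integers(0, k, n)
    # ensure every cluster non-empty
    labels[:k] = np.arange(k)
    return X, labels


class TestPurityMetricsOracle:
    """Hand-written metrics must agree with sklearn to 1e-8."""

    def test_ch_matches_sklearn(self, rng):
        for _ in range(50):
            X, labels = _random_instance(rng)
            assert sp.calinski_harabasz(X, labels) == pytest.approx(
                calinski_harabasz_score(X, labels), abs=1e-8, rel=1e-8
            )

    def test_db_matches_sklearn(self, rng):
        for _ in range(50):
            X, labels = _random_instance(rng)
            assert sp.davies_bouldin_neg(X, labels) == pytest.approx(
                -davies_bouldin_score(X, labels), abs=1e-8, rel=1e-8
            )

    def test_sil_matches_sklearn(self, rng):
        for _ in range(50):
            X, labels = _random_instance(rng)
            assert sp.silhouette_mean(X, labels) == pytest.approx(
                silhouette_score(X, labels), abs=1e-8, rel=1e-8
            )


class TestPurityMetricsHand:
    def test_ch_hand_value(self):
        # two clusters of two points on a line
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([0, 0, 1, 1])
        # centroids 1 and 11, grand mean 6; B = 2*25 + 2*25 = 100; W = 4*1 = 4
        expected = (100 / 1) / (4 / 2)
        assert sp.calinski_harabasz(X, labels) == pytest.approx(expected)

    def test_db_hand_value(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([0, 0, 1, 1])
        # s1 = s2 = 1, centroid distance 10 -> R = 0.2 for both clusters
        assert sp.davies_bouldin_neg(X, labels) == pytest.approx(-0.2)

    def test_sil_brute_force_loop(self, rng):
        X, labels = _random_instance(rng, n=30, d=3, k=3)
        expected = []
        for i in range(len(X)):
            same = (labels == labels[i]) & (np.arange(len(X)) != i)
            if same.sum() == 0:
                expected.append(0.0)
                continue
            a = np.mean([np.linalg.norm(X[i] - X[j]) for j in np.flatnonzero(same)])
            b = min(
                np.mean([np.linalg.norm(X[i] - X[j]) for j in np.flatnonzero(labels == c)])
                for c in np.unique(labels)
                if c != labels[i]
            )
            expected.append((b - a) / max(a, b))
        assert sp.silhouette_mean(X, labels) == pytest.approx(np.mean(expected), abs=1e-10)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        labels = np.array([0, 0, 1])
        brute_a = np.linalg.norm(X[0] - X[1])
        s0 = (5.0 - brute_a) / 5.0
        s1 = (4.9 - brute_a) / 4.9
        assert sp.silhouette_mean(X, labels) == pytest.approx((s0 + s1 + 0.0) / 3)

    def test_k1_is_nan(self):
        X = np.zeros((5, 2))
        labels = np.zeros(5, int)
        assert np.isnan(sp.calinski_harabasz(X, labels))
        assert np.isnan(sp.davies_bouldin_neg(X, labels))
        assert np.isnan(sp.silhouette_mean(X, labels))

    def test_zero_within_dispersion_is_inf(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        labels = np.array([0, 0, 1, 1])
        assert sp.calinski_harabasz(X, labels) == np.inf


class TestFindMarkers:
    def test_hand_toy(self):
        # 2 genes x 4 cells, clusters {0,1} vs {2,3}
        normalized = np.array([[3.0, 5.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        genes = np.array(["gA", "gB"], dtype=object)
        labels = np.array([0, 0, 1, 1])
        markers = sp.find_markers(normalized, genes, labels)
        # cluster 0: gA mean-in 4, mean-out 0 -> log2(5/1); gB -> log2(2/2)=0
        assert markers[0]["gA"] == pytest.approx(np.log2(5.0))
        assert markers[0]["gB"] == pytest.approx(0.0)
        assert list(markers[0].index) == ["gA", "gB"]  # sorted decreasing
        assert markers[1]["gA"] == pytest.approx(np.log2(1.0 / 5.0))

    def test_ties_broken_by_gene_id(self):
        normalized = np.ones((3, 4))
        genes = np.array(["z", "a", "m"], dtype=object)
        markers = sp.find_markers(normalized, genes, np.array([0, 0, 1, 1]))
        assert list(markers[0].index) == ["a", "m", "z"]

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            sp.find_markers(np.ones((2, 3)), np.array(["a", "b"], dtype=object), np.zeros(3, int))


class TestGseaES:
    def test_contiguous_top_block_scores_one(self):
        ranked = pd.Series([3.0, 2.0, 1.0, 0.5, 0.2], index=list("abcde"))
        assert sp.gsea_es(ranked, {"a", "b"}) == pytest.approx(1.0)

    def test_hand_value_with_interleaved_miss(self):
        # hits at positions 0 and 2; weights 5 and 3 (p=1)
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        # running sum after second hit: 8/8 - 1/3 = 2/3 (the max deviation)
        assert sp.gsea_es(ranked, {"a", "c"}) == pytest.approx(2.0 / 3.0)

    def test_tail_loaded_set_is_negative(self):
        ranked = pd.Series(np.arange(20, 0, -1, dtype=float), index=[f"g{i}" for i in range(20)])
        assert sp.gsea_es(ranked, {"g18", "g19"}) < 0

    def test_p0_invariant_under_monotone_rescaling(self, rng):
        vals = np.sort(rng.normal(size=30))[::-1]
        genes = [f"g{i}" for i in range(30)]
        ranked = pd.Series(vals, index=genes)
        rescaled = pd.Series(3.0 * vals + np.sign(vals) * 0.0, index=genes)
        gene_set = set(rng.choice(genes, 8, replace=False))
        assert sp.gsea_es(ranked, gene_set, p=0.0) == pytest.approx(
            sp.gsea_es(rescaled, gene_set, p=0.0)
        )

    def test_no_overlap_is_nan(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        assert np.isnan(sp.gsea_es(ranked, {"x", "y"}))

    def test_full_coverage_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            sp.gsea_es(ranked, {"a", "b"})


class TestGseaNES:
    def _planted(self, rng, n=200, m=15):
        genes = [f"g{i}" for i in range(n)]
        vals = np.sort(rng.normal(size=n))[::-1]
        vals[:m] += 4.0  # strong head loading
        ranked = pd.Series(np.sort(vals)[::-1], index=genes)
        return ranked, set(genes[:m])

    def test_deterministic(self, rng):
        ranked, gene_set = self._planted(rng)
        a = sp.gsea_nes(ranked, gene_set, n_perm=200, seed=3)
        b = sp.gsea_nes(ranked, gene_set, n_perm=200, seed=3)
        assert a == b

    def test_planted_set_exceeds_null(self, rng):
        ranked, gene_set = self._planted(rng)
        assert sp.gsea_nes(ranked, gene_set, n_perm=500, seed=1) > 1.5

    def test_min_permutations_enforced(self, rng):
        ranked, gene_set = self._planted(rng)
        with pytest.raises(ValueError):
            sp.gsea_nes(ranked, gene_set, n_perm=10, seed=0)


class TestGseaMetric:
    def _markers(self, rng, n=600):
        genes = [f"g{i}" for i in range(n)]
        out = {}
        for c in range(2):
            vals = np.sort(rng.normal(size=n))[::-1]
            out[c] = pd.Series(vals, index=rng.permutation(genes))
        return out, genes

    def test_size_filter_bounds_are_strict(self, rng):
        markers, genes = self._markers(rng)
        for size in (5, 10, 500, 600):
            sets = {"s": genes[:size]}
            with pytest.raises(ValueError):
                sp.gsea_metric(markers, sets, n_perm=100, seed=0)
        for size in (11, 499):
            sets = {"s": genes[:size]}
            assert np.isfinite(sp.gsea_metric(markers, sets, n_perm=100, seed=0))

    def test_cluster_relabeling_invariance(self, rng):
        markers, genes = self._markers(rng)
        sets = {"s1": genes[:30], "s2": genes[50:100]}
        v1 = sp.gsea_metric(markers, sets, n_perm=100, seed=5)
        renamed = {"a": markers[0], "b": markers[1]}
        v2 = sp.gsea_metric(renamed, sets, n_perm=100, seed=5)
        assert v1 == pytest.approx(v2)

    def test_filter_gene_sets_uses_universe_intersection(self):
        sets = {"small": [f"g{i}" for i in range(30)], "off": [f"x{i}" for i in range(30)]}
        kept = sp.filter_gene_sets(sets, [f"g{i}" for i in range(100)], min_size=10, max_size=500)
        assert set(kept) == {"small"}


class TestScoreClustering:
    def test_small_dataset_row(self, small_dataset):
        cfg = sp.PipelineConfig("default", "lognorm", 10, 0.5)
        res = sp.run_pipeline(small_dataset.counts, cfg, seed=2)
        sets = sp.generate_gene_sets([small_dataset], n_random=8, seed=0)
        row = sp.score_clustering(small_dataset.counts, res, sets, n_perm=100, seed=1)
        assert row["k"] == res.k
        for m in sp.METRIC_NAMES:
            assert np.isfinite(row[m])
        assert row["db"] < 0 or row["db"] == pytest.approx(0)

    def test_k1_yields_nan_metrics(self, small_dataset):
        res = sp.ClusteringResult(
            kept_cell_ids=small_dataset.counts.cell_ids,
            labels=np.zeros(small_dataset.counts.n_cells, int),
            k=1,
            pipeline_id="p",
            dataset_id="small",
        )
        row = sp.score_clustering(small_dataset.counts, res)
        assert all(np.isnan(row[m]) for m in sp.METRIC_NAMES)


def _toy_table():
    return pd.DataFrame(
        {
            "dataset_id": ["d1"] * 4 + ["d2"] * 4,
            "pipeline_id": ["p1", "p2", "p3", "p4"] * 2,
            "k": [2, 3, 4, 5] * 2,
            "m": [-1.0, 0.0, 2.0, np.nan, 1.0, 2.0, 3.0, 4.0],
        }
    )


class TestTableTransforms:
    def test_scale_hand_values(self):
        tab = sp.scale_within_dataset(_toy_table(), "m")
        x = np.array([-1.0, 0.0, 2.0])
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(tab["m_scaled"][:3], z)
        assert np.isnan(tab["m_scaled"][3])
        # second dataset: mean 2.5, sd ~1.29
        np.testing.assert_allclose(
            tab["m_scaled"][4:], (np.arange(1.0, 5.0) - 2.5) / np.std([1, 2, 3, 4], ddof=1)
        )

    def test_scaled_block_has_zero_mean_unit_sd(self, rng):
        tab = pd.DataFrame(
            {
                "dataset_id": np.repeat(["a", "b"], 20),
                "pipeline_id": [f"p{i}" for i in range(20)] * 2,
                "k": rng.integers(2, 8, 40),
                "m": rng.normal(5, 3, 40),
            }
        )
        out = sp.scale_within_dataset(tab, "m")
        for _, block in out.groupby("dataset_id"):
            assert block["m_scaled"].mean() == pytest.approx(0, abs=1e-12)
            assert block["m_scaled"].std(ddof=1) == pytest.approx(1)

    def test_correct_requires_scaled(self):
        with pytest.raises(KeyError):
            sp.correct_for_k(_toy_table(), "m")

    def test_correct_removes_k_trend(self, rng):
        ks = np.tile(np.arange(2, 12), 6)
        tab = pd.DataFrame(
            {
                "dataset_id": np.repeat([f"d{i}" for i in range(6)], 10),
                "pipeline_id": [f"p{i}" for i in range(10)] * 6,
                "k": ks,
                "m": 3.0 * ks + rng.normal(0, 0.3, 60),
            }
        )
        tab = sp.scale_within_dataset(tab, "m")
        tab = sp.correct_for_k(tab, "m")
        raw_r = abs(np.corrcoef(tab["k"], tab["m_scaled"])[0, 1])
        corr_r = abs(np.corrcoef(tab["k"], tab["m_corrected"])[0, 1])
        assert raw_r > 0.8
        assert corr_r < 0.2

    def test_constant_k_warns_and_centers(self):
        tab = _toy_table().assign(k=3)
        tab = sp.scale_within_dataset(tab, "m")
        with pytest.warns(UserWarning):
            out = sp.correct_for_k(tab, "m")
        block = out[out["dataset_id"] == "d2"]
        assert block["m_corrected"].mean() == pytest.approx(0, abs=1e-12)

    def test_impute_uses_dataset_median_and_flags(self):
        tab = sp.scale_within_dataset(_toy_table(), "m")
        out = sp.impute_missing(tab, "m")
        block = out[out["dataset_id"] == "d1"]
        finite = tab[tab["dataset_id"] == "d1"]["m_scaled"].dropna()
        assert block["m_scaled"].iloc[3] == pytest.approx(np.median(finite))
        assert list(out["m_imputed"]) == [False, False, False, True, False, False, False, False]

    def test_impute_all_missing_block_rejected(self):
        tab = _toy_table()
        tab.loc[tab["dataset_id"] == "d1", "m"] = np.nan
        tab = sp.scale_within_dataset(tab, "m")
        with pytest.raises(ValueError):
            sp.impute_missing(tab, "m")

    def test_purity_metric_names(self):
        assert set(PURITY_METRICS) == {"ch", "db", "sil"}
        assert sp.METRIC_NAMES == ("ch", "db", "sil", "gsea")


class TestARI:
    def test_identical_and_permuted_labels(self, rng):
        labels = rng.integers(0, 4, 100)
        assert sp.adjusted_rand_index(labels, labels) == 1.0
        relabeled = (labels + 1) % 4  # bijective renaming
        assert sp.adjusted_rand_index(labels, relabeled) == 1.0

    def test_independent_labelings_near_zero(self, rng):
        vals = [
            sp.adjusted_rand_index(rng.integers(0, 3, 500), rng.integers(0, 3, 500))
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.adjusted_rand_index([0, 1], [0, 1, 2])


class TestPurityInput:
    def test_shape_and_content(self, small_dataset):
        cfg = sp.PipelineConfig("default", "lognorm", 10, 0.5)
        res = sp.run_pipeline(small_dataset.counts, cfg, seed=2)
        X = sp.purity_input(small_dataset.counts, res, n_hvgs=100)
        assert X.shape == (len(res.kept_cell_ids), 100)
        assert X.min() >= 0  # log1p of counts
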