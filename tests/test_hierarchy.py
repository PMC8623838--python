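"""Hierarchy construction: Ward oracle, gap thresholds, cuts, nesting, recovery."""

import json
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcnnhar.hierarchy import (
    CentroidSet,
    Dendrogram,
    FeatureMatrix,
    HierarchicalLabelSet,
    HierarchyBuildConfig,
    build_hierarchy,
    class_centroids,
    flat_clusters,
    gap_thresholds,
    reduce_pca,
    relabel,
    split_for_hierarchy,
    ward_dendrogram,
)
from bcnnhar.synthetic import (
    SyntheticDatasetConfig,
    default_benchmark_specs,
    generate_dataset,
    window_summary_features,
)
from conftest import TRUE_GROUPS


def ward_bruteforce(points: np.ndarray) -> list[float]:
    """Greedy minimum-dESS agglomeration; heights sqrt(2 * dESS)."""

    def ess(idx):
        p = points[list(idx)]
        return float(((p - p.mean(axis=0)) ** 2).sum())

    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        heights.append(np.sqrt(2 * delta))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


class TestWard:
    def test_two_centroids_merge_at_distance(self):
        d = ward_dendrogram(CentroidSet([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(d.heights, [5.0])

    def test_worked_1d_example(self):
        d = ward_dendrogram(CentroidSet([[0.0], [1.0], [10.0]]))
        np.testing.assert_allclose(d.heights, [1.0, np.sqrt(2 * 60.1667)], atol=1e-3)

    def test_matches_bruteforce_dess_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = rng.integers(3, 8)
            pts = rng.normal(size=(c, rng.integers(1, 5)))
            got = ward_dendrogram(CentroidSet(pts)).heights
            np.testing.assert_allclose(got, ward_bruteforce(pts), atol=1e-8)

    def test_heights_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = ward_dendrogram(CentroidSet(rng.normal(size=(10, 4))))
            assert (np.diff(d.heights) >= -1e-12).all()


def _toy_dendrogram(heights):
    """Hand-assembled valid linkage: leaves merged pairwise then chained."""
    n = len(heights) + 1
    Z = np.zeros((len(heights), 4))
    next_id = n
    # chain: (0,1) then (prev, k)
    prev = 0
    for i, h in enumerate(heights):
        if i == 0:
            Z[i] = [0, 1, h, 2]
        else:
            Z[i] = [prev, i + 1, h, i + 2]
        prev = next_id
        next_id += 1
    return Dendrogram(Z)


class TestGapThresholds:
    def test_worked_example(self):
        d = _toy_dendrogram([1.0, 1.1, 3.0, 3.2, 9.0])
        thresholds, selected = gap_thresholds(d, 2, 0.01)
        np.testing.assert_allclose(thresholds, [3.21, 1.11])
        assert selected == [3, 1]

    def test_single_level_uses_largest_gap(self):
        d = _toy_dendrogram([0.5, 0.7, 5.0])
        thresholds, selected = gap_thresholds(d, 1, 0.01)
        assert selected == [1] and abs(thresholds[0] - 0.71) < 1e-9

    def test_tie_prefers_coarser_cut(self):
        d = _toy_dendrogram([1.0, 2.0, 3.0, 4.0])  # all gaps equal
        _, selected = gap_thresholds(d, 2, 0.1)
        assert selected == [2, 1]

    def test_too_many_levels_rejected(self):
        d = _toy_dendrogram([1.0, 2.0])
        with pytest.raises(ValueError, match="cannot cut"):
            gap_thresholds(d, 2)


class TestFlatClusters:
    def test_extremes(self):
        d = _toy_dendrogram([1.0, 2.0, 3.0])
        assert flat_clusters(d, 0.5).tolist() == [0, 1, 2, 3]  # below first merge
        assert flat_clusters(d, 3.5).tolist() == [0, 0, 0, 0]  # above last merge

    def test_worked_cut(self):
        d = ward_dendrogram(CentroidSet([[0.0], [1.0], [10.0]]))
        assert flat_clusters(d, 1.5).tolist() == [0, 0, 1]

    def test_renumbering_by_smallest_member(self):
        # centroids chosen so classes (2,3) merge first, then (0,1)
        d = ward_dendrogram(CentroidSet([[0.0], [0.4], [10.0], [10.1]]))
        m = flat_clusters(d, 1.0)
        assert m.tolist() == [0, 0, 1, 1]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_cluster_count_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        d = ward_dendrogram(CentroidSet(rng.normal(size=(7, 3))))
        ts = np.linspace(0, d.heights[-1] * 1.1, 25)
        counts = [flat_clusters(d, t).max() + 1 for t in ts]
        assert (np.diff(counts) <= 0).all()


class TestPCA:
    def test_top_component_variance_is_largest_eigenvalue(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(5, 3)) @ np.diag([3.0, 1.0, 0.3])
            fm = reduce_pca(FeatureMatrix(X, np.zeros(5, int)), d=3)
            top_var = fm.F[:, 0].var(ddof=1)
            eig = np.linalg.eigvalsh(np.cov(X.T)).max()
            assert abs(top_var - eig) < 1e-8

    def test_full_dimension_preserves_distances(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        fm = reduce_pca(FeatureMatrix(X, np.zeros(20, int)), d=6)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(fm.F), pdist(X), atol=1e-6)

    def test_infeasible_d_clamped(self):
        X = np.random.default_rng(2).normal(size=(4, 3))
        fm = reduce_pca(FeatureMatrix(X, np.zeros(4, int)), d=64)
        assert fm.F.shape[1] == 3


class TestCentroidsSplitRelabel:
    def test_centroid_values(self):
        fm = FeatureMatrix([[1.0, 1.0], [3.0, 3.0], [5.0, 0.0]], [0, 0, 1])
        cs = class_centroids(fm)
        np.testing.assert_allclose(cs.F_center, [[2.0, 2.0], [5.0, 0.0]])

    def test_empty_class_named_in_error(self):
        fm = FeatureMatrix([[1.0], [2.0]], [0, 0])
        with pytest.raises(ValueError, match="class 1"):
            class_centroids(fm, n_classes=2)

    def test_split_sizes_and_stratification(self, benchmark_ds):
        d_pre, d_adp = split_for_hierarchy(benchmark_ds, 0.5, seed=0)
        n = len(benchmark_ds)
        assert len(d_pre) == round(0.5 * n)
        assert len(d_pre) + len(d_adp) == n
        for c in range(6):
            a = (d_pre.targets == c).sum()
            b = (d_adp.targets == c).sum()
            assert abs(a - b) <= 1

    def test_relabel(self):
        y = np.array([0, 2, 1, 2])
        np.testing.assert_array_equal(relabel(y, np.array([0, 1, 2])), y)
        np.testing.assert_array_equal(relabel(y, np.array([0, 0, 0])), 0)
        m2, g = np.array([0, 1, 1]), np.array([1, 0])
        np.testing.assert_array_equal(relabel(relabel(y, m2), g), relabel(y, g[m2]))
        with pytest.raises(KeyError):
            relabel(np.array([5]), np.array([0, 1]))


class TestBuildHierarchy:
    def test_oracle_features_recover_groups(self, benchmark_cfg, benchmark_ds):
        """With true generative parameters as features, Level 2 = latent groups."""
        from conftest import make_oracle_features

        oracle = make_oracle_features(benchmark_ds, benchmark_cfg)
        hier = build_hierarchy(
            benchmark_ds, HierarchyBuildConfig(n_coarse_levels=2, seed=0), feature_fn=oracle
        )
        assert hier.level_partition(2) == TRUE_GROUPS

    def test_summary_features_recover_groups(self, benchmark_ds):
        hier = build_hierarchy(
            benchmark_ds,
            HierarchyBuildConfig(n_coarse_levels=2, seed=0),
            feature_fn=window_summary_features,
        )
        assert hier.level_partition(2) == TRUE_GROUPS

    def test_deterministic(self, benchmark_ds):
        cfg = HierarchyBuildConfig(n_coarse_levels=2, seed=3)
        a = build_hierarchy(benchmark_ds, cfg, feature_fn=window_summary_features)
        b = build_hierarchy(benchmark_ds, cfg, feature_fn=window_summary_features)
        for ma, mb in zip(a.maps, b.maps):
            np.testing.assert_array_equal(ma, mb)

    def test_nesting_holds_on_random_datasets(self):
        """Every constructed hierarchy is a chain of nested partitions."""
        specs = tuple(default_benchmark_specs())
        for seed in range(10):
            cfg = SyntheticDatasetConfig(
                specs, n_subjects=3, windows_per_subject_per_class=6, seed=seed
            )
            ds = generate_dataset(cfg)
            hier = build_hierarchy(
                ds, HierarchyBuildConfig(n_coarse_levels=2, seed=seed),
                feature_fn=window_summary_features,
            )
            hier.validate_nesting()  # raises on violation
            counts = hier.level_class_counts
            assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_stage_named_on_failure(self, benchmark_ds):
        cfg = HierarchyBuildConfig(n_coarse_levels=5, seed=0)  # too many levels for C=6
        with pytest.raises(ValueError, match="stage"):
            build_hierarchy(benchmark_ds, cfg, feature_fn=window_summary_features)


class TestHierarchicalLabelSet:
    def test_nesting_violation_detected(self):
        maps = [np.array([0, 0, 1, 1]), np.array([0, 1, 1, 2])]  # fine class 1 spans coarse 0,1
        with pytest.raises(ValueError, match="nesting"):
            HierarchicalLabelSet(maps, np.arange(4), list("abcd"))

    def test_json_roundtrip(self, tmp_path):
        maps = [np.array([0, 0, 1, 1]), np.array([0, 1, 2, 2])]
        hier = HierarchicalLabelSet(maps, np.arange(4), list("abcd"), [2.0, 1.0], [0.5, 1.0, 3.0])
        path = tmp_path / "h.json"
        hier.to_json(path)
        back = HierarchicalLabelSet.from_json(path, np.arange(4))
        for ma, mb in zip(hier.maps, back.maps):
            np.testing.assert_array_equal(ma, mb)
        assert back.thresholds == [2.0, 1.0]

    def test_hand_crafted_hierarchy_accepted(self):
        payload = {
            "class_names": ["stay", "walk", "stup", "stdown", "jog", "skip"],
            "levels": [
                {"stay": 0, "walk": 1, "stup": 1, "stdown": 1, "jog": 1, "skip": 1},
                {"stay": 0, "walk": 1, "stup": 1, "stdown": 1, "jog": 2, "skip": 2},
            ],
        }
        hier = HierarchicalLabelSet.from_json(json.dumps(payload))
        assert hier.level_class_counts == (2, 3, 6)

    def test_hier_labels_for_training(self):
        maps = [np.array([0, 0, 1])]
        hier = HierarchicalLabelSet(maps, np.array([0, 1, 2, 2]), list("abc"))
        labels = hier.hier_labels()
        np.testing.assert_array_equal(labels.levels[0], [0, 0, 1, 1])
        np.testing.assert_array_equal(labels.levels[1], [0, 1, 2, 2])
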