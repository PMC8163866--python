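"""Feature stacking, k-means segmentation, background rejection."""

import itertools

import numpy as np
import pytest

from mirscan import (
    FtirConfig,
    ScannerConfig,
    extract_cluster,
    kmeans_segment,
    reject_background_clusters,
    simulate_mir_scan,
    stack_features,
    unstack_labels,
)
from mirscan.acquisition import HyperCube
from mirscan.errors import ConfigurationError, DataError, LookupError_
from mirscan.preprocess import to_absorbance
from mirscan.segment import FeatureTable, LabelMap, best_matching_cluster


def table(matrix, shape=None):
    matrix = np.asarray(matrix, dtype=float)
    if shape is None:
        shape = (matrix.shape[0], 1)
    return FeatureTable(matrix=matrix, shape=shape, feature_axis=np.arange(matrix.shape[1]))


def brute_force_wcss(points, k):
    """Minimal within-cluster sum of squares over all assignments (tiny n)."""
    n = len(points)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        wcss = 0.0
        for c in range(k):
            members = points[np.array(assignment) == c]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best


class TestStackFeatures:
    def test_rasters_stack_to_table(self, rng):
        images = [rng.random((2, 2)) for _ in range(3)]
        t = stack_features(images)
        assert t.matrix.shape == (4, 3)
        assert t.shape == (2, 2)

    def test_cube_stacks_to_table(self, rng):
        cube = HyperCube(rng.random((2, 2, 7)), np.linspace(4000, 3000, 7), 20.0)
        t = stack_features(cube)
        assert t.matrix.shape == (4, 7)
        assert np.array_equal(t.feature_axis, cube.wavenumbers)

    def test_unstack_round_trip(self, rng):
        x = rng.random((3, 5))
        t = stack_features([x])
        assert np.array_equal(unstack_labels(t.matrix[:, 0], t.shape), x)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            stack_features([rng.random((2, 2)), rng.random((3, 2))])


class TestKmeans:
    def test_two_separated_groups_recovered_exactly(self):
        # brute-force assignment oracle on a tiny problem
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0.0, 0.05, (6, 2)), rng.normal(5.0, 0.05, (6, 2))]
        )
        t = table(pts, shape=(12, 1))
        for seed in (0, 1, 2):
            lm = kmeans_segment(t, k=2, seed=seed)
            labels = lm.labels.ravel()
            assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
            assert labels[0] != labels[6]
        # and the WCSS it achieves equals the enumerated optimum
        wcss = sum(
            ((pts[labels == c] - pts[labels == c].mean(axis=0)) ** 2).sum()
            for c in (0, 1)
        )
        assert wcss == pytest.approx(brute_force_wcss(pts, 2))

    def test_identical_features_single_cluster(self):
        t = table(np.full((10, 3), 0.5), shape=(10, 1))
        lm = kmeans_segment(t, k=1, seed=0)
        assert set(lm.labels.ravel()) == {0}
        assert np.allclose(lm.centroids, 0.5)

    def test_k_equal_n_distinct_points_zero_wcss(self):
        pts = np.arange(6, dtype=float).reshape(6, 1)
        lm = kmeans_segment(table(pts, shape=(6, 1)), k=6, seed=0)
        assert len(set(lm.labels.ravel())) == 6

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(3)
        pts = rng.random((200, 2))
        t = table(pts, shape=(200, 1))

        def wcss(lm):
            flat = lm.labels.ravel()
            return sum(
                ((pts[flat == c] - lm.centroids[c]) ** 2).sum() for c in range(lm.k)
            )

        single = wcss(kmeans_segment(t, k=5, seed=0, restarts=1))
        many = wcss(kmeans_segment(t, k=5, seed=0, restarts=10))
        assert many <= single + 1e-9

    def test_labels_ordered_by_descending_size(self):
        pts = np.concatenate([np.zeros(30), np.ones(10)]).reshape(-1, 1)
        lm = kmeans_segment(table(pts, shape=(40, 1)), k=2, seed=0)
        flat = lm.labels.ravel()
        assert (flat == 0).sum() > (flat == 1).sum()

    def test_deterministic_for_fixed_seed(self, rng):
        t = table(rng.random((100, 3)), shape=(100, 1))
        a = kmeans_segment(t, k=4, seed=7)
        b = kmeans_segment(t, k=4, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.centroids, b.centroids)

    def test_k_exceeding_distinct_points_rejected(self):
        t = table(np.zeros((5, 1)), shape=(5, 1))
        with pytest.raises(DataError):
            kmeans_segment(t, k=2, seed=0)
        with pytest.raises(ConfigurationError):
            kmeans_segment(t, k=6, seed=0)


class TestRejection:
    def lm(self, labels, k):
        labels = np.asarray(labels)
        return LabelMap(labels=labels, k=k, centroids=np.zeros((k, 1)), seed=0)

    def test_pure_background_cluster_rejected_tissue_kept(self):
        labels = np.array([[0, 0], [1, 1]])
        mask = np.array([[False, False], [True, True]])
        kept = reject_background_clusters(self.lm(labels, 2), mask)
        assert set(kept.labels.ravel()) == {-1, 0}
        assert (kept.labels == -1).sum() == 2
        assert kept.rejected == {0}

    def test_majority_threshold_counting_oracle(self):
        # cluster 1: 6 of 10 pixels off-tissue -> fraction 0.6
        labels = np.zeros((1, 20), dtype=int)
        labels[0, 10:] = 1
        mask = np.ones((1, 20), dtype=bool)
        mask[0, 10:16] = False
        rejected = reject_background_clusters(self.lm(labels, 2), mask, majority=0.5)
        assert 1 in rejected.rejected
        kept = reject_background_clusters(self.lm(labels, 2), mask, majority=0.7)
        assert kept.rejected == frozenset()

    def test_all_rejected_is_an_error(self):
        labels = np.zeros((2, 2), dtype=int)
        mask = np.zeros((2, 2), dtype=bool)
        with pytest.raises(DataError):
            reject_background_clusters(self.lm(labels, 1), mask)


class TestExtract:
    def test_union_of_kept_clusters_is_tissue_partition(self, brain_phantom):
        scan = simulate_mir_scan(brain_phantom, ScannerConfig(noise_sd=0.0), seed=0)
        images = [
            to_absorbance(scan.images[l.id], scan.background[l.id]).values
            for l in scan.config.lasers
        ]
        lm = kmeans_segment(stack_features(images), k=4, seed=0)
        kept = reject_background_clusters(lm, brain_phantom.tissue_mask())
        union = np.zeros(kept.labels.shape, dtype=bool)
        for cid in kept.kept_ids():
            m = extract_cluster(kept, cid)
            assert not (union & m).any()  # disjoint
            union |= m
        assert np.array_equal(union, kept.labels >= 0)

    def test_rejected_or_unknown_id_is_lookup_error(self):
        lm = LabelMap(
            labels=np.array([[0, -1]]), k=2, centroids=np.zeros((2, 1)), seed=0,
            rejected=frozenset({1}),
        )
        with pytest.raises(LookupError_):
            extract_cluster(lm, -1)
        with pytest.raises(LookupError_):
            extract_cluster(lm, 5)


class TestNoiselessClassRecovery:
    def test_noiseless_brain_phantom_perfect_dice_at_k_classes_plus_one(
        self, brain_phantom
    ):
        # features are exactly class-constant, so k = classes + 1 recovers
        # every class with Dice = 1
        scan = simulate_mir_scan(brain_phantom, ScannerConfig(noise_sd=0.0), seed=0)
        images = [
            to_absorbance(scan.images[l.id], scan.background[l.id]).values
            for l in scan.config.lasers
        ]
        lm = kmeans_segment(stack_features(images), k=4, seed=0)
        kept = reject_background_clusters(lm, brain_phantom.tissue_mask())
        for cls in (1, 2, 3):
            _, dice = best_matching_cluster(kept, brain_phantom.labels == cls)
            assert dice == pytest.approx(1.0)
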