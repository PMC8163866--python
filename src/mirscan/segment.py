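"""k-means segmentation of per-pixel spectral features with background rejection.

Both modalities reduce to a FeatureTable — one row per pixel in row-major
order, one column per spectral channel.  Clustering is plain k-means
(k-means++ seeding, Lloyd iterations, best of several restarts); the cluster
count k is a user parameter exactly as in practice (no model selection).
Clusters dominated by off-tissue pixels are rejected by an explicit
mask-majority rule and encoded as −1, mirroring the rejection of
background-related clusters in the measurement workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from mirscan.acquisition import HyperCube
from mirscan.errors import ConfigurationError, DataError, LookupError_
from mirscan.preprocess import AbsorbanceImage


@dataclass
class FeatureTable:
    """n_pixels × n_features matrix plus the raster shape it unflattens to."""

    matrix: np.ndarray
    shape: tuple[int, int]
    feature_axis: np.ndarray  # wavenumbers, one per feature column

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_axis = np.asarray(self.feature_axis, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise DataError("feature matrix must be n_pixels x n_features with >= 1 feature")
        if self.matrix.shape[0] != self.shape[0] * self.shape[1]:
            raise DataError("row count does not match the raster shape")
        if self.feature_axis.size != self.matrix.shape[1]:
            raise DataError("feature axis length does not match feature count")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("feature matrix contains non-finite entries")


@dataclass
class LabelMap:
    """Cluster raster: −1 = rejected/background, 0..k−1 = kept clusters."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    seed: int
    rejected: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.all(np.isfinite(self.centroids)):
            raise DataError("centroids must be finite")

    def kept_ids(self) -> list[int]:
        ids = set(np.unique(self.labels)) - {-1}
        return sorted(int(i) for i in ids)


def stack_features(
    source: Sequence[AbsorbanceImage] | Sequence[np.ndarray] | HyperCube,
    feature_axis: Sequence[float] | None = None,
) -> FeatureTable:
    """Stack co-registered channels into a per-pixel feature table.

    Accepts a HyperCube or a sequence of 2D rasters / AbsorbanceImages; rows
    follow row-major pixel order so the table unflattens to the source grid.
    """
    if isinstance(source, HyperCube):
        r, c, b = source.shape
        return FeatureTable(
            matrix=source.data.reshape(r * c, b),
            shape=(r, c),
            feature_axis=source.wavenumbers,
        )
    arrays = []
    axis = []
    for item in source:
        if isinstance(item, AbsorbanceImage):
            arrays.append(item.values)
            axis.append(item.wavenumber)
        else:
            arrays.append(np.asarray(item, dtype=float))
            axis.append(np.nan)
    if feature_axis is not None:
        axis = list(feature_axis)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise DataError(f"channel shapes differ: {sorted(shapes)}")
    shape = arrays[0].shape
    matrix = np.stack([a.ravel() for a in arrays], axis=1)
    return FeatureTable(matrix=matrix, shape=shape, feature_axis=np.asarray(axis, dtype=float))


def unstack_labels(labels_flat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Reshape a flat per-pixel vector back onto its source raster."""
    return np.asarray(labels_flat).reshape(shape)


def kmeans_segment(
    features: FeatureTable,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-6,
) -> LabelMap:
    """Cluster pixels by k-means and return a stable, size-ordered label map.

    Lloyd iterations with k-means++ seeding, best of ``restarts`` by
    within-cluster sum of squares; deterministic for a fixed seed.  Clusters
    are relabelled in descending size so label ids are stable across runs.
    """
    n = features.matrix.shape[0]
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n < k:
        raise ConfigurationError(f"k = {k} exceeds the pixel count {n}")
    n_distinct = np.unique(features.matrix, axis=0).shape[0]
    if k > n_distinct:
        raise DataError(f"k = {k} exceeds the number of distinct feature vectors {n_distinct}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(features.matrix)
    labels = km.labels_
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")  # descending size, stable ties
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return LabelMap(
        labels=unstack_labels(remap[labels], features.shape),
        k=k,
        centroids=km.cluster_centers_[order],
        seed=seed,
    )


def reject_background_clusters(
    label_map: LabelMap, tissue_mask: np.ndarray, majority: float = 0.5
) -> LabelMap:
    """Reject clusters whose off-tissue pixel fraction exceeds ``majority``.

    Rejected clusters get id −1; the kept clusters are re-indexed densely,
    preserving their size order, and their centroid rows are retained.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != label_map.labels.shape:
        raise DataError("tissue mask shape does not match the label map")
    if not 0.5 <= majority <= 1.0:
        raise ConfigurationError("majority must be in [0.5, 1]")
    labels = label_map.labels
    new = np.full_like(labels, -1)
    kept_centroids = []
    rejected = []
    next_id = 0
    for cid in range(label_map.k):
        members = labels == cid
        total = int(members.sum())
        if total == 0:
            rejected.append(cid)
            continue
        off = int((members & ~tissue_mask).sum())
        if off / total > majority:
            rejected.append(cid)
        else:
            new[members] = next_id
            kept_centroids.append(label_map.centroids[cid])
            next_id += 1
    if next_id == 0:
        raise DataError("every cluster was rejected as background")
    return LabelMap(
        labels=new,
        k=label_map.k,
        centroids=np.asarray(kept_centroids),
        seed=label_map.seed,
        rejected=frozenset(rejected),
    )


def extract_cluster(label_map: LabelMap, cluster_id: int) -> np.ndarray:
    """Binary mask of one kept cluster's pixels."""
    if cluster_id == -1 or cluster_id not in label_map.kept_ids():
        raise LookupError_(f"cluster {cluster_id} is rejected or does not exist")
    return label_map.labels == cluster_id


def best_matching_cluster(label_map: LabelMap, truth_mask: np.ndarray) -> tuple[int, float]:
    """Kept cluster with maximal Dice overlap against a truth mask.

    Returns (cluster id, Dice coefficient).
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    best_id, best_dice = -1, -1.0
    for cid in label_map.kept_ids():
        m = label_map.labels == cid
        inter = np.logical_and(m, truth_mask).sum()
        denom = m.sum() + truth_mask.sum()
        dice = 2.0 * inter / denom if denom else 0.0
        if dice > best_dice:
            best_id, best_dice = cid, dice
    if best_id < 0:
        raise DataError("label map has no kept clusters")
    return best_id, float(best_dice)
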