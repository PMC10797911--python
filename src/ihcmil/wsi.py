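"""Translating a TMA-trained model to whole-slide images.

A slide cannot be scored as one giant bag by a model trained on ~45-patch
cores, so the slide's foreground patch coordinates are k-means-clustered
into core-sized convex "mini-bags" (k = round(n / target_size), k-means on
patch centers: convex cells tile the tissue without the overlap circular
windows would have). Each mini-bag is scored by the trained model(s) and the
slide-level prediction is the median of the mini-bag predictions; the score
distribution and per-patch attention are exported for inspection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import Bag, GatedAttentionParams, bag_attention, predict_bag
from .patches import InstanceEmbedding, Patch


@dataclasses.dataclass
class MiniBagPartition:
    """Disjoint, exhaustive k-means clusters of foreground patch indices."""

    clusters: list[np.ndarray]  # index arrays into the patch list
    centroids: np.ndarray  # k x 2 (row, col)
    target_size: int
    patches: list[Patch]

    def __post_init__(self) -> None:
        idx = np.concatenate(self.clusters) if self.clusters else np.array([])
        assert len(idx) == len(set(idx.tolist())), "clusters overlap"
        assert len(idx) == len(self.patches), "clusters do not cover all patches"
        assert all(len(c) > 0 for c in self.clusters), "empty cluster"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def mean_size(self) -> float:
        return len(self.patches) / len(self.clusters)


@dataclasses.dataclass
class SlideScore:
    cluster_predictions: np.ndarray  # percent per mini-bag
    slide_prediction: float  # the median
    marker: str

    def __post_init__(self) -> None:
        assert np.isclose(
            self.slide_prediction, float(np.median(self.cluster_predictions))
        )


def cluster_coordinates(
    foreground: list[Patch], target_size: int = 45, seed: int = 0
) -> MiniBagPartition:
    """Partition foreground patches into k = max(1, round(n/target_size))
    spatial clusters by k-means on patch centers (k-means++ init, 10
    restarts, fixed seed). Empty clusters, should k-means produce any, are
    dropped so the partition invariant holds.
    """
    if len(foreground) == 0:
        raise ValueError("no foreground patches to cluster")
    n = len(foreground)
    k = max(1, round(n / target_size))
    coords = np.array([p.center for p in foreground])
    if k == 1:
        return MiniBagPartition(
            clusters=[np.arange(n)],
            centroids=coords.mean(axis=0, keepdims=True),
            target_size=target_size,
            patches=list(foreground),
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    clusters, centroids = [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if len(members):
            clusters.append(members)
            centroids.append(km.cluster_centers_[c])
    return MiniBagPartition(
        clusters=clusters,
        centroids=np.asarray(centroids),
        target_size=target_size,
        patches=list(foreground),
    )


def _minibag(partition: MiniBagPartition, embeddings, cluster_idx: int,
             marker: str) -> Bag:
    members = partition.clusters[cluster_idx]
    X = np.stack([embeddings[i].vector for i in members])
    return Bag(bag_id=f"minibag{cluster_idx}", instances=X, label=0.0, marker=marker)


def score_slide(
    partition: MiniBagPartition,
    embeddings: list[InstanceEmbedding],
    models: GatedAttentionParams | list[GatedAttentionParams],
    marker: str = "c-MYC",
    pooling: str = "attention",
) -> SlideScore:
    """Score each mini-bag and take the median as the slide prediction.

    ``models`` may be a single trained model or the list of fold models
    from cross-validation; with several, each mini-bag's prediction is the
    mean over models (an even-count median is the mean of the two central
    values).
    """
    if len(embeddings) != len(partition.patches):
        raise ValueError(
            f"{len(embeddings)} embeddings vs {len(partition.patches)} "
            "partitioned patches"
        )
    if isinstance(models, GatedAttentionParams):
        models = [models]
    preds = np.empty(partition.n_clusters)
    for ci in range(partition.n_clusters):
        bag = _minibag(partition, embeddings, ci, marker)
        preds[ci] = np.mean([predict_bag(bag, m, pooling) for m in models])
    return SlideScore(
        cluster_predictions=preds,
        slide_prediction=float(np.median(preds)),
        marker=marker,
    )


def attention_heatmap(
    partition: MiniBagPartition,
    embeddings: list[InstanceEmbedding],
    model: GatedAttentionParams,
    image_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch attention painted at patch footprints.

    Within each mini-bag the raw weights form a softmax simplex (sum 1).
    Returns ``(display, raw)``: the display raster is min-max rescaled to
    [0, 1] over the slide; the raw raster keeps the softmax weights.
    Background stays 0 in both.
    """
    raw = np.zeros(image_shape, dtype=np.float64)
    for ci in range(partition.n_clusters):
        members = partition.clusters[ci]
        bag = _minibag(partition, embeddings, ci, "c-MYC")
        a = bag_attention(bag, model)
        for local, i in enumerate(members):
            p = partition.patches[i]
            raw[p.row : p.row + p.size, p.col : p.col + p.size] = a[local]
    display = raw.copy()
    if display.max() > display.min():
        display = (display - display.min()) / (display.max() - display.min())
    return display, raw


def patch_attention_table(
    partition: MiniBagPartition,
    embeddings: list[InstanceEmbedding],
    model: GatedAttentionParams,
) -> pd.DataFrame:
    """Raw per-patch attention weights with their mini-bag ids."""
    rows = []
    for ci in range(partition.n_clusters):
        members = partition.clusters[ci]
        bag = _minibag(partition, embeddings, ci, "c-MYC")
        a = bag_attention(bag, model)
        for local, i in enumerate(members):
            p = partition.patches[i]
            rows.append(
                {"cluster_id": ci, "patch_id": int(i), "row": p.row,
                 "col": p.col, "attention": float(a[local])}
            )
    return pd.DataFrame(rows)


def cluster_score_map(
    partition: MiniBagPartition,
    slide_score: SlideScore,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Grayscale raster: each cluster footprint filled with its score
    (0 -> black, 100 -> white); background black."""
    out = np.zeros(image_shape, dtype=np.uint8)
    for ci, pred in enumerate(slide_score.cluster_predictions):
        level = int(round(np.clip(pred, 0, 100) / 100.0 * 255))
        for i in partition.clusters[ci]:
            p = partition.patches[i]
            out[p.row : p.row + p.size, p.col : p.col + p.size] = level
    return out


def cluster_table(partition: MiniBagPartition, score: SlideScore,
                  slide_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "cluster_id": np.arange(partition.n_clusters),
            "n_patches": [len(c) for c in partition.clusters],
            "score": score.cluster_predictions,
        }
    )
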