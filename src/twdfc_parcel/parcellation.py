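"""Hard parcellation of the bundle by k-means in component space.

Each in-mask voxel is a point in the k-dimensional space of group component
z-weights; k-means (Euclidean, k-means++ with multiple restarts) partitions
the voxels, and the mean silhouette coefficient over a candidate range picks
the number of clusters c. Labels are canonicalized by ascending dorsoventral
(z) centroid coordinate: cluster 1 is the most ventral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .gica import ComponentSet
from .imaging import VolumeGrid


@dataclass
class Parcellation:
    labels_volume: np.ndarray  # 3-D int field, 1..c inside mask, 0 outside
    labels: np.ndarray  # (V,) labels over mask voxels, 1..c
    c: int
    centroids_mm: np.ndarray  # (c, 3)
    silhouette_by_c: dict[int, float]
    feature_space: np.ndarray  # (V, k)


def feature_matrix(components: ComponentSet) -> np.ndarray:
    """(V, k) matrix: row v holds voxel v's weight in each group z-map."""
    if components.k < 2:
        raise ValueError("clustering needs k >= 2 components")
    return components.group_zmaps.T.copy()


def kmeans_cluster(
    features: np.ndarray, c: int, seed: int, n_init: int = 50
) -> np.ndarray:
    """Best-of-n_init k-means labels (0..c-1), deterministic given seed."""
    features = np.asarray(features, dtype=float)
    if c > features.shape[0]:
        raise ValueError("more clusters than points")
    km = KMeans(n_clusters=c, n_init=n_init, random_state=seed)
    return km.fit_predict(features)


def silhouette_select(
    features: np.ndarray,
    c_range: range | list[int] = range(2, 7),
    seed: int = 0,
    n_init: int = 50,
) -> tuple[int, dict[int, float]]:
    """Mean silhouette per candidate c; returns (argmax c, scores).

    Ties break toward the smallest c. Candidates larger than V - 1 are
    skipped.
    """
    features = np.asarray(features, dtype=float)
    scores: dict[int, float] = {}
    for c in c_range:
        if not (2 <= c <= features.shape[0] - 1):
            continue
        labels = kmeans_cluster(features, c, seed, n_init=n_init)
        scores[c] = float(silhouette_score(features, labels))
    if not scores:
        raise ValueError("no admissible cluster count in range")
    best = max(scores.values())
    chosen = min(c for c, s in scores.items() if s >= best - 1e-12)
    return chosen, scores


def relabel_dorsoventral(
    labels: np.ndarray, voxel_coords_mm: np.ndarray, axis: int = 2
) -> np.ndarray:
    """Relabel clusters 1..c by ascending mean coordinate along ``axis``
    (ventral -> dorsal for the z axis)."""
    uniq = np.unique(labels)
    order = np.argsort([voxel_coords_mm[labels == u, axis].mean() for u in uniq])
    new = np.empty_like(labels)
    for rank, idx in enumerate(order):
        new[labels == uniq[idx]] = rank + 1
    return new


def cluster_centroids(
    labels: np.ndarray, voxel_coords_mm: np.ndarray
) -> np.ndarray:
    """World-mm centroid of each cluster's member voxel centers."""
    uniq = np.unique(labels)
    out = np.empty((len(uniq), 3))
    for i, u in enumerate(uniq):
        members = voxel_coords_mm[labels == u]
        if members.size == 0:
            raise ValueError(f"cluster {u} is empty")
        out[i] = members.mean(axis=0)
    return out


def cluster_component_profile(
    labels: np.ndarray, components: ComponentSet
) -> pd.DataFrame:
    """Mean and sd of each component's z-weights within each cluster."""
    feats = components.group_zmaps  # (k, V)
    rows = []
    for u in np.unique(labels):
        sel = labels == u
        for comp in range(components.k):
            rows.append(
                {
                    "cluster": int(u),
                    "component": comp + 1,
                    "mean_z": float(feats[comp, sel].mean()),
                    "sd_z": float(feats[comp, sel].std()),
                    "n_voxels": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def parcellate(
    components: ComponentSet,
    grid: VolumeGrid,
    mask_voxels: np.ndarray,
    c_range: range | list[int] = range(2, 7),
    seed: int = 0,
    c: int | None = None,
    n_init: int = 50,
) -> Parcellation:
    """Silhouette-guided k-means parcellation over the group mask.

    mask_voxels: (V, 3) voxel indices corresponding to the component maps'
    voxel axis. If ``c`` is given the silhouette scan is still reported but
    the cluster count is forced.
    """
    features = feature_matrix(components)
    chosen, scores = silhouette_select(features, c_range, seed, n_init=n_init)
    if c is not None:
        chosen = c
    raw = kmeans_cluster(features, chosen, seed, n_init=n_init)
    coords = grid.voxel_centers_mm(mask_voxels)
    labels = relabel_dorsoventral(raw + 1, coords)
    vol = np.zeros(grid.shape, dtype=np.int32)
    vol[mask_voxels[:, 0], mask_voxels[:, 1], mask_voxels[:, 2]] = labels
    return Parcellation(
        labels_volume=vol,
        labels=labels,
        c=chosen,
        centroids_mm=cluster_centroids(labels, coords),
        silhouette_by_c=scores,
        feature_space=features,
    )
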