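"""Reference-sample and representative-sample selection.

The normalization target is chosen computationally: of all panel images,
the one whose red-to-blue mean-intensity ratio is closest to 1 (a balanced
H&E appearance; hematoxylin expresses in blue, eosin in red).

Representative samples for a panel are chosen by clustering: per-channel
lαβ histograms are used as features, projected to two principal
components, clustered with k-means, and the member nearest each cluster
centroid represents its cluster.  A within-cluster-sum-of-squares curve is
emitted as an elbow diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .exceptions import DegenerateImageError, InvalidImageError
from .metrics import lab_channel_ranges, lab_histograms

__all__ = [
    "RBRatio",
    "HistogramFeature",
    "RepresentativeSet",
    "rb_ratio",
    "select_reference",
    "histogram_features",
    "panel_features",
    "select_representatives",
]


@dataclass(frozen=True)
class RBRatio:
    """Red-to-blue mean-intensity ratio of one sample."""

    sample_id: str
    ratio: float


@dataclass(frozen=True)
class HistogramFeature:
    """Concatenated normalized lαβ channel histograms of one sample."""

    sample_id: str
    vector: np.ndarray


@dataclass
class RepresentativeSet:
    """K-means representatives with their diagnostics."""

    cluster_assignments: dict[str, int]
    representatives: list[str]
    pca_coords: dict[str, np.ndarray]
    wcss: list[float] = field(default_factory=list)


def rb_ratio(img: np.ndarray) -> float:
    """Mean red intensity divided by mean blue intensity."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"expected H x W x 3 image, got shape {arr.shape}")
    blue = arr[..., 2].mean()
    if blue == 0.0:
        raise DegenerateImageError("blue channel mean is zero; R/B undefined")
    return float(arr[..., 0].mean() / blue)


def select_reference(
    panel: Sequence[np.ndarray], ids: Sequence[str] | None = None
) -> tuple[int, list[RBRatio]]:
    """Pick the panel image whose R/B ratio is closest to 1.

    Ties break toward the lowest index.  The full ratio list is returned
    for plotting the panel's color spread.
    """
    if len(panel) == 0:
        raise InvalidImageError("panel must contain at least one image")
    if ids is None:
        ids = [str(i) for i in range(len(panel))]
    ratios = [RBRatio(sid, rb_ratio(img)) for sid, img in zip(ids, panel)]
    deviations = np.array([abs(r.ratio - 1.0) for r in ratios])
    return int(np.argmin(deviations)), ratios


def histogram_features(
    img: np.ndarray,
    bins: int = 64,
    ranges: np.ndarray | None = None,
    sample_id: str = "",
) -> HistogramFeature:
    """Concatenated per-channel lαβ histograms, each block summing to 1."""
    hset = lab_histograms(img, bins, ranges)
    return HistogramFeature(sample_id, hset.hists.reshape(-1).copy())


def panel_features(
    panel: Sequence[np.ndarray],
    ids: Sequence[str] | None = None,
    bins: int = 64,
) -> list[HistogramFeature]:
    """Features for a whole panel over shared (panel-global) channel ranges."""
    if ids is None:
        ids = [str(i) for i in range(len(panel))]
    ranges = lab_channel_ranges(panel)
    return [
        histogram_features(img, bins, ranges, sid) for sid, img in zip(ids, panel)
    ]


def select_representatives(
    features: Sequence[HistogramFeature],
    k: int = 8,
    seed: int = 0,
    max_elbow_k: int = 12,
) -> RepresentativeSet:
    """Cluster samples in 2-D PCA space and pick one representative each.

    PCA centers the feature matrix without variance scaling and keeps the
    first two components (ordered by explained variance).  Seeded k-means
    (10 restarts, best inertia) clusters the 2-D coordinates; the member
    nearest its centroid (Euclidean) represents each cluster.  The WCSS
    curve for k = 1..min(max_elbow_k, n) is attached as an elbow
    diagnostic.
    """
    n = len(features)
    if k < 1:
        raise InvalidImageError("k must be a positive integer")
    if n < k:
        raise InvalidImageError(f"need at least k={k} samples, got {n}")
    x = np.stack([f.vector for f in features])
    ids = [f.sample_id for f in features]
    coords = PCA(n_components=2, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    assignments = {sid: int(lbl) for sid, lbl in zip(ids, km.labels_)}
    representatives = []
    for cluster in range(k):
        members = np.flatnonzero(km.labels_ == cluster)
        dists = np.linalg.norm(coords[members] - km.cluster_centers_[cluster], axis=1)
        representatives.append(ids[members[int(np.argmin(dists))]])
    wcss = [
        float(KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(coords).inertia_)
        for kk in range(1, min(max_elbow_k, n) + 1)
    ]
    return RepresentativeSet(
        cluster_assignments=assignments,
        representatives=representatives,
        pca_coords={sid: coords[i] for i, sid in enumerate(ids)},
        wcss=wcss,
    )
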