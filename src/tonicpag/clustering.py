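"""Response clustering and spatial statistics for escape-related activity.

Mean time-warped responses are ternarized by double thresholding
(y < -0.2 Z -> -1, y > 0.2 Z -> +1, else 0), embedded by PCA, and clustered
with K-means on the first 3 component scores; the cluster count is chosen by
the highest mean silhouette over k = 2..8 (inertia reported for the elbow
view). The arbitrary K-means labels are mapped to stable identities by the
sign of each cluster's mean response between the reaction and escape-stop
anchors: positive -> cluster 1 (ramp-to-termination), negative -> cluster 2
(dip at escape onset).

Timing statistics locate the response extremum of each neuron's mean warped
trace (peak for cluster 1, trough for cluster 2) relative to escape end, and
compare extremum-time distributions with each behavioural anchor
(one-sample t-tests for cluster 1, sign tests for cluster 2,
Holm-Bonferroni corrected). A label-permutation test on the convex-hull
Jaccard index (intersection over union of the two clusters' hull areas in
the imaging field of view) asks whether the clusters are spatially
segregated beyond chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Polygon, box
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .spiketrain import InsufficientDataError

__all__ = [
    "ClusterResult",
    "SpatialOverlap",
    "ternarize",
    "embed_pca",
    "cluster_k",
    "extremum_timing",
    "timing_tests",
    "spatial_overlap",
    "write_labels_csv",
]

TERNARY_LO = -0.2
TERNARY_HI = 0.2
N_PCA_COMPONENTS = 3
KMEANS_N_INIT = 50
SILHOUETTE_FLOOR = 0.2


def ternarize(
    traces: np.ndarray, lo: float = TERNARY_LO, hi: float = TERNARY_HI
) -> np.ndarray:
    """Double-threshold map to {-1, 0, +1}; boundaries are strict."""
    if not lo < hi:
        raise ValueError("lo threshold must be below hi")
    x = np.asarray(traces, dtype=float)
    return np.where(x > hi, 1.0, np.where(x < lo, -1.0, 0.0))


def embed_pca(
    matrix: np.ndarray, n_components: int = N_PCA_COMPONENTS
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred PCA scores and explained-variance fractions."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < max(4, n_components + 1):
        raise InsufficientDataError(
            f"PCA needs more than {max(4, n_components + 1)} neurons, got {x.shape[0]}"
        )
    if x.shape[1] < 4:
        raise InsufficientDataError("PCA needs at least 4 time points")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # identity labels, 1 = ramp-like, 2 = dip-like, ...
    chosen_k: int
    silhouette_by_k: dict[int, float]
    inertia_by_k: dict[int, float]
    clusterable: bool
    identity_of_kmeans_label: dict[int, int] = field(default_factory=dict)


def cluster_k(
    scores: np.ndarray,
    window_means: np.ndarray | None = None,
    k_range: Sequence[int] = range(2, 9),
    n_init: int = KMEANS_N_INIT,
    seed: int | None = None,
) -> ClusterResult:
    """K-means over a k range with silhouette-based model selection.

    ``window_means`` (per-neuron mean response between reaction and escape
    stop) maps K-means labels to stable identities: clusters are ranked by
    their mean window response, most positive first, so "cluster 1" is the
    ramp-like group and "cluster 2" the dip-like group regardless of seed.
    Degenerate inputs (all rows identical) yield a flagged single-cluster
    result.
    """
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        return ClusterResult(
            labels=np.ones(n, dtype=int),
            chosen_k=1,
            silhouette_by_k={},
            inertia_by_k={},
            clusterable=False,
        )
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range must contain values in [2, n_neurons - 1]")
    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(x)
        fits[k] = km
        inertia[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(x, lab)) if len(set(lab)) > 1 else -1.0
    chosen_k = max(sil, key=sil.__getitem__)
    raw = fits[chosen_k].labels_
    identity_map: dict[int, int] = {}
    if window_means is not None:
        wm = np.asarray(window_means, dtype=float)
        order = sorted(
            range(chosen_k), key=lambda c: -float(wm[raw == c].mean())
        )
        identity_map = {c: i + 1 for i, c in enumerate(order)}
    else:
        identity_map = {c: c + 1 for c in range(chosen_k)}
    labels = np.array([identity_map[c] for c in raw])
    return ClusterResult(
        labels=labels,
        chosen_k=chosen_k,
        silhouette_by_k=sil,
        inertia_by_k=inertia,
        clusterable=max(sil.values()) >= SILHOUETTE_FLOOR,
        identity_of_kmeans_label=identity_map,
    )


def extremum_timing(
    mean_trace: Sequence[float],
    grid: Sequence[float],
    identity: int,
    escape_stop_time: float,
) -> float:
    """Time of the response extremum relative to escape end.

    Peak (argmax) for cluster 1, trough (argmin) for cluster 2; ties break
    to the earliest extremum.
    """
    x = np.asarray(mean_trace, dtype=float)
    t = np.asarray(grid, dtype=float)
    idx = int(np.argmax(x)) if identity == 1 else int(np.argmin(x))
    return float(t[idx] - escape_stop_time)


def timing_tests(
    extremum_times: Sequence[float],
    anchors: Mapping[str, float],
    kind: Literal["t", "sign"] = "t",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare extremum times (relative to escape end) with event anchors.

    Per anchor: a one-sample two-tailed t-test (cluster 1 convention) or a
    sign test (cluster 2) of the times against the anchor's time, then
    Holm-Bonferroni correction across anchors. ``anchors`` maps names to
    times on the same relative-to-escape-end scale.
    """
    x = np.asarray(extremum_times, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("timing tests need at least 3 neurons")
    names = list(anchors)
    raw_p = []
    for name in names:
        mu = anchors[name]
        if kind == "t":
            raw_p.append(float(stats.ttest_1samp(x, mu).pvalue))
        else:
            diffs = x - mu
            n_pos = int(np.sum(diffs > 0))
            n_neg = int(np.sum(diffs < 0))
            n = n_pos + n_neg
            p = 1.0 if n == 0 else float(
                stats.binomtest(min(n_pos, n_neg), n, 0.5).pvalue
            )
            raw_p.append(p)
    reject, corrected, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    return pd.DataFrame(
        {
            "anchor": names,
            "anchor_time_s": [anchors[n] for n in names],
            "p_raw": raw_p,
            "p_holm": corrected,
            "significant": reject,
        }
    )


@dataclass(frozen=True)
class SpatialOverlap:
    jaccard: float
    permutation_p: float
    n_permutations: int
    null_mean: float
    hull_fallback: bool = False


def _hull_polygon(points: np.ndarray) -> tuple[Polygon, bool]:
    """Convex hull as a shapely polygon; degenerate (collinear) point sets
    fall back to the bounding box, flagged."""
    try:
        hull = ConvexHull(points)
        return Polygon(points[hull.vertices]), False
    except QhullError:
        x0, y0 = points.min(axis=0)
        x1, y1 = points.max(axis=0)
        eps = 1e-9
        return box(x0 - eps, y0 - eps, x1 + eps, y1 + eps), True


def _jaccard(points: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    ids = np.unique(labels)
    polys = []
    fallback = False
    for c in ids[:2]:
        poly, fb = _hull_polygon(points[labels == c])
        fallback |= fb
        polys.append(poly)
    inter = polys[0].intersection(polys[1]).area
    union = polys[0].union(polys[1]).area
    return (inter / union if union > 0 else 0.0), fallback


def spatial_overlap(
    centroids: np.ndarray,
    labels: Sequence[int],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SpatialOverlap:
    """Permutation test on the spatial overlap of two clusters in a FOV.

    Convex hulls are fitted to each cluster's mask centroids and the Jaccard
    index (hull intersection area over union area) computed. The null is
    built by shuffling cluster labels; the two-sided p-value counts
    permutations whose |J - null mean| is at least the observed deviation,
    with the +1 correction.
    """
    pts = np.asarray(centroids, dtype=float)
    lab = np.asarray(labels)
    ids, counts = np.unique(lab, return_counts=True)
    if len(ids) != 2:
        raise ValueError("spatial_overlap expects exactly two clusters")
    if counts.min() < 3:
        raise InsufficientDataError("each cluster needs >= 3 neurons for a hull")
    observed, fallback = _jaccard(pts, lab)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(lab)
        null[i], fb = _jaccard(pts, perm)
        fallback |= fb
    null_mean = float(null.mean())
    dev = abs(observed - null_mean)
    p = (1 + int(np.sum(np.abs(null - null_mean) >= dev - 1e-12))) / (
        1 + n_permutations
    )
    return SpatialOverlap(
        jaccard=float(observed),
        permutation_p=float(p),
        n_permutations=n_permutations,
        null_mean=null_mean,
        hull_fallback=fallback,
    )


def write_labels_csv(
    labels: Sequence[int], neuron_ids: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame({"neuron_id": list(neuron_ids), "cluster": list(labels)}).to_csv(
        path, index=False
    )
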