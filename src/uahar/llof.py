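"""Label-based local outlier factor (LLOF) sample filtering.

After automatic annotation, each sample carries a cluster label, and a
local-outlier-factor score is computed with the neighbor search
restricted to the sample's own cluster.  Scores near 1 mean the sample
sits inside a tight region of its cluster; larger scores flag
low-confidence samples (annotation errors, transition windows), which
are removed before the per-class Gaussians are fitted.

For a sample C with same-cluster k-neighborhood N(C):

* k-distance: distance to the k-th nearest same-cluster neighbor
  (distance ties at the k-th rank are all included in N(C));
* reachability of D from C: max(k-distance(C), d(C, D));
* reachability density rho(C) = |N(C)| / sum_{D in N(C)} max(k-distance(D), d(C, D));
* LLOF(C) = mean_{D in N(C)} rho(D) / rho(C).

Restricted to one cluster this is exactly the textbook LOF of that
cluster.  Degenerate duplicate-point densities (0/0) score 1, the
non-outlier value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .seeded_kmeans import LabeledFeatureSet


@dataclass
class LLOFParams:
    k_neighbors: int = 20
    eps1: float = 1.5

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not self.eps1 > 0:
            raise ValueError("eps1 must be > 0")


def knn_distance_in_cluster(point: np.ndarray, cluster: np.ndarray, k: int) -> float:
    """Distance from ``point`` to its k-th nearest neighbor among ``cluster``
    (the point itself must not be in ``cluster``)."""
    cluster = np.atleast_2d(np.asarray(cluster, dtype=float))
    if len(cluster) < k:
        raise ValueError(
            f"cluster has {len(cluster)} other members but k={k}; "
            "skip LLOF filtering for this cluster"
        )
    d = np.sort(np.linalg.norm(cluster - np.asarray(point, dtype=float), axis=1))
    return float(d[k - 1])


def reachability_distance(
    point_c: np.ndarray, point_d: np.ndarray, k: int, cluster: np.ndarray
) -> float:
    """max(k-distance of C within its cluster, d(C, D))."""
    kd = knn_distance_in_cluster(point_c, cluster, k)
    return float(max(kd, np.linalg.norm(np.asarray(point_c, float) - np.asarray(point_d, float))))


def _cluster_lof(sub: np.ndarray, k: int) -> np.ndarray:
    """Textbook LOF of the points in ``sub`` against each other."""
    m = len(sub)
    dist = cdist(sub, sub)
    np.fill_diagonal(dist, np.inf)
    order = np.sort(dist, axis=1)
    kdist = order[:, k - 1]
    # tie-inclusive k-neighborhoods
    neighborhoods = [np.nonzero(dist[i] <= kdist[i])[0] for i in range(m)]

    lrd = np.empty(m)
    for i, nbrs in enumerate(neighborhoods):
        reach = np.maximum(kdist[nbrs], dist[i, nbrs])
        total = reach.sum()
        lrd[i] = np.inf if total == 0.0 else len(nbrs) / total

    scores = np.empty(m)
    for i, nbrs in enumerate(neighborhoods):
        num = lrd[nbrs].mean()
        if np.isinf(lrd[i]):
            # duplicate-point degeneracy: inf/inf (0/0 densities) -> 1; finite/inf -> 0
            scores[i] = 1.0 if np.isinf(num) else 0.0
        else:
            scores[i] = num / lrd[i]
    return scores


def llof_scores(
    labeled: LabeledFeatureSet, params: LLOFParams | None = None
) -> np.ndarray:
    """LLOF score for every sample; clusters with <= k members get score 1
    (pass-through) with a warning."""
    params = params or LLOFParams()
    X, y = labeled.X, labeled.y
    scores = np.ones(len(X))
    for cls in dict.fromkeys(str(lab) for lab in y):  # preserves first-seen order
        idx = np.nonzero(np.array([str(lab) == cls for lab in y]))[0]
        if len(idx) <= params.k_neighbors:
            warnings.warn(
                f"cluster {cls!r} has only {len(idx)} samples (k={params.k_neighbors}); "
                "left unfiltered",
                stacklevel=2,
            )
            continue
        scores[idx] = _cluster_lof(X[idx], params.k_neighbors)
    return scores


def llof_score(
    point_index: int, labeled: LabeledFeatureSet, params: LLOFParams | None = None
) -> float:
    """Score of one sample of the labeled set (convenience wrapper)."""
    return float(llof_scores(labeled, params)[point_index])


def filter_outliers(
    labeled: LabeledFeatureSet, params: LLOFParams | None = None
) -> tuple[LabeledFeatureSet, LabeledFeatureSet, np.ndarray]:
    """Single-pass removal of samples with LLOF > eps1.

    Scores are computed once against the original set (no re-scoring).
    Returns (kept set, removed set, scores over the original set).
    """
    params = params or LLOFParams()
    scores = llof_scores(labeled, params)
    keep = scores <= params.eps1
    kept = LabeledFeatureSet(labeled.X[keep], labeled.y[keep], provenance="filtered")
    removed = LabeledFeatureSet(labeled.X[~keep], labeled.y[~keep], provenance="filtered")
    return kept, removed, scores
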