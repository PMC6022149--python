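"""Seeded K-Means automatic annotation.

Standard K-Means is sensitive to initialization, and its clusters carry
no labels.  Here the initial centroids are the labeled class centroids
of a pre-collected ("seed") dataset from other users; because activity
classes occupy similar regions of feature space across people, the
converged clusters inherit those labels — which annotates a new user's
unlabeled windows automatically.  K is fixed at 3 (LIA/MIA/VIA); falls
are never a cluster because training sessions contain no falls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ACTIVITY_CLASSES = ("LIA", "MIA", "VIA")


@dataclass
class SeededCentroids:
    """K labeled centroids used to initialize (and annotate) clustering."""

    centers: np.ndarray          # (K, d)
    labels: tuple[str, ...]      # length K, distinct

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.labels = tuple(self.labels)
        if self.centers.ndim != 2 or len(self.centers) != len(self.labels):
            raise ValueError("one centroid per label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("centroid labels must be distinct")


@dataclass
class LabeledFeatureSet:
    """Feature vectors with per-vector activity labels."""

    X: np.ndarray                # (m, d)
    y: np.ndarray                # (m,) labels
    provenance: str = "annotated"   # annotated | filtered | seed

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class KMeansResult:
    labeled: LabeledFeatureSet
    n_iter: int
    centers: np.ndarray
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def seed_centroids(
    X: np.ndarray,
    y: np.ndarray,
    classes: tuple[str, ...] = ACTIVITY_CLASSES,
) -> SeededCentroids:
    """Class-mean centroids of a pre-labeled dataset; every class must occur."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    centers = []
    for cls in classes:
        mask = np.array([str(lab) == cls for lab in y])
        if not mask.any():
            raise ValueError(f"seed dataset has no samples for class {cls!r}")
        centers.append(X[mask].mean(axis=0))
    return SeededCentroids(np.array(centers), classes)


def _objective(X: np.ndarray, centers: np.ndarray, assign: np.ndarray) -> float:
    return float(np.sum((X - centers[assign]) ** 2))


def kmeans_annotate(
    X: np.ndarray,
    seeds: SeededCentroids,
    max_iter: int = 100,
) -> KMeansResult:
    """Lloyd iterations from the seeded centroids; labels inherited through
    centroid identity.

    Assignment uses squared Euclidean distance with ties broken toward the
    lowest cluster index.  A cluster that loses all members keeps its
    previous centroid (the labeled anchor).  Iteration stops at an
    assignment fixpoint; hitting ``max_iter`` first records a warning but
    still returns the result.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot annotate an empty feature set")
    if X.shape[1] != seeds.centers.shape[1]:
        raise ValueError("feature dimension does not match seed centroids")

    centers = seeds.centers.copy()
    assign = None
    converged = False
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)  # argmin ties -> lowest index
        history.append(_objective(X, centers, new_assign))
        if assign is not None and np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        for k in range(len(centers)):
            members = X[assign == k]
            if len(members):
                centers[k] = members.mean(axis=0)
            # empty cluster: keep previous centroid (labeled anchor)
    if not converged:
        warnings.warn(
            f"seeded K-Means hit max_iter={max_iter} without an assignment fixpoint",
            stacklevel=2,
        )
    labels = np.array([seeds.labels[k] for k in assign], dtype=object)
    return KMeansResult(
        labeled=LabeledFeatureSet(X, labels, provenance="annotated"),
        n_iter=n_iter,
        centers=centers,
        converged=converged,
        objective_history=history,
    )
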