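"""State-adapted cluster-validity indices.

Global validity indices are the wrong yardstick for time-continuous states:
non-adjacent states may legitimately coincide (states can alternate).  The
indices here are therefore computed on every pair of *time-adjacent* states,
each pair treated as a two-cluster dataset, and averaged over pairs:

* Silhouette coefficient (mean s(i) over both clusters),
* Calinski-Harabasz index (between/within variance ratio with its
  degrees-of-freedom factors),
* Davies-Bouldin index,
* Ward distance  (n_a n_b / (n_a + n_b)) * ||mu_a - mu_b||^2,
* centroid distance ||mu_a - mu_b||.

A point in a singleton cluster has silhouette 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

from ._partition import SegmentPartition

__all__ = [
    "PairQuality",
    "StateAdaptedScores",
    "ward_distance_sets",
    "centroid_distance_sets",
    "pair_quality",
    "state_adapted_scores",
    "state_adapted_silhouette",
]

MEASURES = ("silhouette", "calinski_harabasz", "davies_bouldin", "ward_distance", "centroid_distance")


@dataclass(frozen=True)
class PairQuality:
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    ward_distance: float
    centroid_distance: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


@dataclass(frozen=True)
class StateAdaptedScores:
    """Per-adjacent-pair qualities and their unweighted means."""

    pairs: list[PairQuality]

    def mean(self, measure: str) -> float:
        return float(np.mean([getattr(p, measure) for p in self.pairs]))

    @property
    def silhouette(self) -> float:
        return self.mean("silhouette")

    def as_dict(self) -> dict:
        return {
            "mean": {m: self.mean(m) for m in MEASURES},
            "pairs": [p.as_dict() for p in self.pairs],
        }


def ward_distance_sets(A: np.ndarray, B: np.ndarray) -> float:
    """Ward distance between two point sets: the within-cluster-variance
    increase caused by merging them."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("clusters must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    na, nb = A.shape[0], B.shape[0]
    diff = A.mean(axis=0) - B.mean(axis=0)
    return float(na * nb / (na + nb) * diff @ diff)


def centroid_distance_sets(A: np.ndarray, B: np.ndarray) -> float:
    """Euclidean distance between cluster centroids (size-independent)."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("clusters must be non-empty")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0)))


def pair_quality(X: np.ndarray, seg_a, seg_b) -> PairQuality:
    """All five measures on the two-cluster dataset formed by two segments.

    ``seg_a``/``seg_b`` are (start, stop) tuples in epoch-index space over
    ``X`` (epochs x features).
    """
    a = X[seg_a[0]:seg_a[1]]
    b = X[seg_b[0]:seg_b[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("segments must be non-empty")
    Z = np.vstack([a, b])
    labels = np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)])
    if len(a) == 1 and len(b) == 1:
        sil = 0.0  # both points are singletons
    else:
        sil = float(silhouette_samples(Z, labels).mean())
    cd = centroid_distance_sets(a, b)
    within = float(np.sum((a - a.mean(axis=0)) ** 2) + np.sum((b - b.mean(axis=0)) ** 2))
    if within == 0.0:
        ch = 0.0 if cd == 0.0 else np.inf
    else:
        ch = float(calinski_harabasz_score(Z, labels))
    # coincident centroids: similarity ratio diverges (poorest possible pair);
    # two separated singletons have zero scatter, hence a perfect 0 score
    if cd == 0.0:
        db = np.inf
    elif len(a) == 1 and len(b) == 1:
        db = 0.0
    else:
        db = float(davies_bouldin_score(Z, labels))
    return PairQuality(
        silhouette=sil,
        calinski_harabasz=ch,
        davies_bouldin=db,
        ward_distance=ward_distance_sets(a, b),
        centroid_distance=cd,
    )


def state_adapted_scores(X: np.ndarray, partition: SegmentPartition) -> StateAdaptedScores:
    """All five measures averaged over adjacent state pairs."""
    segs = partition.segments
    if len(segs) < 2:
        raise ValueError("state-adapted scores need at least two states")
    return StateAdaptedScores([pair_quality(X, segs[i], segs[i + 1]) for i in range(len(segs) - 1)])


def state_adapted_silhouette(X: np.ndarray, partition: SegmentPartition) -> float:
    """Mean silhouette over adjacent state pairs (the selection criterion)."""
    segs = partition.segments
    if len(segs) < 2:
        raise ValueError("need at least two states")
    vals = []
    for i in range(len(segs) - 1):
        a = X[segs[i][0]:segs[i][1]]
        b = X[segs[i + 1][0]:segs[i + 1][1]]
        if len(a) == 1 and len(b) == 1:
            vals.append(0.0)
            continue
        Z = np.vstack([a, b])
        labels = np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)])
        vals.append(float(silhouette_samples(Z, labels).mean()))
    return float(np.mean(vals))
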