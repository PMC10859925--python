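"""The State-Detecting Algorithm (SDA).

An unsupervised, ensemble change-point method that partitions a
multichannel time series (represented as one feature vector per epoch) into
time-continuous functional states.  It works in two phases:

**Phase 1** — for every hyperparameter triple (N, K, L) in a grid:
agglomerative Ward clustering restricted by a temporal connectivity graph
(epochs within K of each other are connected) is cut at N clusters; the
sorted cluster boundaries tile the epoch axis into time-continuous
segments; segments of length <= L are merged into their Ward-nearest
neighbour; adjacent segments are then merged while the smallest adjacent
Ward distance D_min <= W * D_avg (the running mean over adjacent pairs).
The interior boundaries of the resulting partition are that triple's
boundary candidates.

**Phase 2** — for every (N_max, K_max, L), the candidates of all triples
with N <= N_max and K <= K_max at that L are pooled into a multiset (the
multiplicity of an index measures its stability).  The multiset is
clustered in 1-D with KMeans (each cluster count N_KM) and DBSCAN (each
radius E_DBS on the index scale normalized by the epoch count), and each
cluster emits mean/median/mode centers rounded to integer epochs.  For each
final state count, the candidate boundary set maximizing the state-adapted
silhouette wins.  The optimal number of states is left to the caller (an
expert decision); the detector reports every state count it can produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN, KMeans, ward_tree
from sklearn.utils import check_array, check_random_state

from ._partition import SegmentPartition
from .quality_metrics import state_adapted_scores, state_adapted_silhouette

__all__ = [
    "ClusterSummary",
    "SDAHyperGrid",
    "ward_distance",
    "centroid_distance",
    "ward_connectivity_cluster",
    "clusters_to_segments",
    "merge_short_segments",
    "merge_close_segments",
    "phase1",
    "build_joint_candidates",
    "cluster_candidates",
    "select_partition",
    "StateDetector",
    "run_sda",
    "SegmentPartition",
]


@dataclass(frozen=True)
class ClusterSummary:
    """Size, centroid and (optionally) member set of a cluster."""

    n: int
    centroid: np.ndarray
    members: frozenset | None = None

    @classmethod
    def from_points(cls, X: np.ndarray, members=None) -> "ClusterSummary":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cluster must be non-empty")
        return cls(X.shape[0], X.mean(axis=0), frozenset(members) if members is not None else None)


def ward_distance(a: ClusterSummary, b: ClusterSummary) -> float:
    """Within-cluster-variance increase caused by merging a and b."""
    if a.n <= 0 or b.n <= 0:
        raise ValueError("clusters must be non-empty")
    if a.centroid.shape != b.centroid.shape:
        raise ValueError("dimension mismatch")
    diff = a.centroid - b.centroid
    return float(a.n * b.n / (a.n + b.n) * diff @ diff)


def centroid_distance(a: ClusterSummary, b: ClusterSummary) -> float:
    """Euclidean distance between cluster centers (size-independent)."""
    if a.centroid.shape != b.centroid.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a.centroid - b.centroid))


@dataclass(frozen=True)
class SDAHyperGrid:
    """The hyperparameter ensemble of the detector.

    Defaults are the study ranges: N in [2, 20], K in [20, 50] (epochs,
    i.e. seconds at 1-s epochs, over the retained-epoch sequence),
    L in {0, 20, 40, 60}, W = 0.3, N_max in {10, 15, 20},
    K_max in {35, 40, 45, 50}, N_KM in [2, 15],
    E_DBS in {0.02, 0.025, 0.03} (on the normalized index scale),
    centers mean/median/mode.
    """

    N_range: tuple[int, ...] = tuple(range(2, 21))
    K_range: tuple[int, ...] = tuple(range(20, 51))
    L_values: tuple[int, ...] = (0, 20, 40, 60)
    W: float = 0.3
    N_max_values: tuple[int, ...] = (10, 15, 20)
    K_max_values: tuple[int, ...] = (35, 40, 45, 50)
    N_KM_range: tuple[int, ...] = tuple(range(2, 16))
    E_DBS_values: tuple[float, ...] = (0.02, 0.025, 0.03)
    center_types: tuple[str, ...] = ("mean", "median", "mode")
    dbscan_min_samples: int = 5

    def __post_init__(self) -> None:
        for name in ("N_range", "K_range", "L_values", "N_max_values", "K_max_values", "N_KM_range", "E_DBS_values", "center_types"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if not 0 < self.W < 1:
            raise ValueError(f"W must lie in (0, 1), got {self.W}")
        if max(self.N_max_values) > max(self.N_range):
            raise ValueError("N_max exceeds the N range")
        if max(self.K_max_values) > max(self.K_range):
            raise ValueError("K_max exceeds the K range")
        if any(n < 2 for n in self.N_range) or any(k < 1 for k in self.K_range):
            raise ValueError("need N >= 2 and K >= 1")

    @property
    def n_phase1_triples(self) -> int:
        return len(self.N_range) * len(self.K_range) * len(self.L_values)

    def phase1_triples(self):
        for N in self.N_range:
            for K in self.K_range:
                for L in self.L_values:
                    yield (N, K, L)

    @classmethod
    def small(cls) -> "SDAHyperGrid":
        """A reduced ensemble for quick runs on short recordings."""
        return cls(
            N_range=tuple(range(2, 13)),
            K_range=tuple(range(20, 41, 4)),
            L_values=(0, 20),
            N_max_values=(8, 12),
            K_max_values=(32, 40),
            N_KM_range=tuple(range(2, 13)),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SDAHyperGrid":
        def _seq(v):
            return tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**{k: _seq(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# phase 1: connectivity-constrained Ward clustering -> segment partitions


def _band_connectivity(n: int, K: int) -> sparse.csr_matrix:
    """Sparse adjacency: epochs i, j connected iff 0 < |i - j| <= K."""
    offsets = [o for o in range(-K, K + 1) if o != 0]
    return sparse.diags_array(
        [np.ones(n - abs(o)) for o in offsets], offsets=offsets, format="csr"
    )


def _cut_ward_tree(children: np.ndarray, n_leaves: int, n_clusters: int) -> np.ndarray:
    """Labels from the first ``n_leaves - n_clusters`` merges of a linkage tree."""
    n_used = n_leaves - n_clusters
    if n_used < 0:
        raise ValueError(f"cannot cut {n_leaves} leaves into {n_clusters} clusters")
    parent = np.full(n_leaves + n_used, -1, dtype=np.int64)
    for i in range(n_used):
        a, b = children[i]
        parent[a] = parent[b] = n_leaves + i
    labels = np.empty(n_leaves, dtype=np.int64)
    root_label: dict[int, int] = {}
    for leaf in range(n_leaves):
        node = leaf
        path = []
        while parent[node] != -1:
            path.append(node)
            node = parent[node]
        for p in path:  # path compression: point directly at the root
            parent[p] = node
        parent[node] = -1
        labels[leaf] = root_label.setdefault(node, len(root_label))
    return labels


def ward_connectivity_cluster(X: np.ndarray, N: int, K: int) -> np.ndarray:
    """Ward agglomeration where merges require a temporal edge (|i-j| <= K).

    Returns a label per epoch with exactly N clusters.  With K >= n_epochs
    the constraint is vacuous and the result equals unconstrained Ward
    clustering.
    """
    X = check_array(X)
    n = X.shape[0]
    if N < 2 or K < 1:
        raise ValueError("need N >= 2 and K >= 1")
    if n <= N:
        if n == N:
            return np.arange(n)
        raise ValueError(f"cannot form {N} clusters from {n} epochs")
    children = ward_tree(X, connectivity=_band_connectivity(n, min(K, n)))[0]
    return _cut_ward_tree(children, n, N)


def clusters_to_segments(labels: np.ndarray) -> SegmentPartition:
    """Boundary set {min(c), max(c)+1 over clusters} -> time-continuous tiling.

    Clusters produced under the connectivity constraint need not be
    contiguous in time; interleaved clusters yield a finer tiling than
    either cluster alone.
    """
    labels = np.asarray(labels)
    n = len(labels)
    bounds = {0, n}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        bounds.add(int(idx[0]))
        bounds.add(int(idx[-1]) + 1)
    return SegmentPartition(sorted(bounds))


def _prefix_sums(X: np.ndarray) -> np.ndarray:
    return np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X, axis=0)])


def _segment_summary(prefix: np.ndarray, lo: int, hi: int) -> tuple[int, np.ndarray]:
    n = hi - lo
    return n, (prefix[hi] - prefix[lo]) / n


def _adjacent_ward(prefix: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Ward distance for every adjacent segment pair of a partition."""
    stats = [_segment_summary(prefix, boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]
    out = np.empty(len(stats) - 1)
    for i in range(len(stats) - 1):
        (na, ma), (nb, mb) = stats[i], stats[i + 1]
        d = ma - mb
        out[i] = na * nb / (na + nb) * (d @ d)
    return out


def merge_short_segments(p: SegmentPartition, X: np.ndarray, L: int, *, _prefix=None) -> SegmentPartition:
    """Merge every segment of length <= L into its Ward-nearest neighbour.

    The shortest offending segment is processed first (ties broken
    leftmost); the loop repeats until all segments are longer than L or a
    single segment remains.  L = 0 is a no-op.
    """
    if L <= 0:
        return p
    prefix = _prefix if _prefix is not None else _prefix_sums(X)
    b = list(p.boundaries)
    while len(b) > 2:
        lengths = np.diff(b)
        offending = np.flatnonzero(lengths <= L)
        if len(offending) == 0:
            break
        i = offending[np.argmin(lengths[offending])]  # shortest, ties leftmost
        ni, mi = _segment_summary(prefix, b[i], b[i + 1])
        d_left = d_right = np.inf
        if i > 0:
            nl, ml = _segment_summary(prefix, b[i - 1], b[i])
            dl = mi - ml
            d_left = ni * nl / (ni + nl) * (dl @ dl)
        if i < len(b) - 2:
            nr, mr = _segment_summary(prefix, b[i + 1], b[i + 2])
            dr = mi - mr
            d_right = ni * nr / (ni + nr) * (dr @ dr)
        if d_left <= d_right:
            del b[i]  # merge into the left neighbour
        else:
            del b[i + 1]
    return SegmentPartition(b)


def merge_close_segments(p: SegmentPartition, X: np.ndarray, W: float, *, _prefix=None) -> SegmentPartition:
    """Merge the closest adjacent pair while D_min <= W * D_avg.

    D_avg is recomputed over the current partition after every merge; the
    loop stops when the minimum adjacent Ward distance exceeds the
    proportion W of the running average, or a single segment remains.  With
    exactly two segments D_min = D_avg, so no merge happens for W < 1.
    """
    if not 0 < W < 1:
        raise ValueError(f"W must lie in (0, 1), got {W}")
    prefix = _prefix if _prefix is not None else _prefix_sums(X)
    b = np.array(p.boundaries)
    while len(b) > 2:
        d = _adjacent_ward(prefix, b)
        i = int(np.argmin(d))
        if d[i] > W * d.mean():
            break
        b = np.delete(b, i + 1)
    return SegmentPartition(b)


def phase1(X: np.ndarray, grid: SDAHyperGrid | None = None) -> dict[tuple[int, int, int], np.ndarray]:
    """Run phase 1 over the full (N, K, L) grid.

    Returns a map (N, K, L) -> sorted interior boundary candidates.  One
    linkage tree is built per K and cut at every N, which is equivalent to
    running the constrained agglomeration per (N, K) pair.
    """
    grid = grid or SDAHyperGrid()
    X = check_array(X)
    n = X.shape[0]
    if n <= max(grid.N_range):
        raise ValueError(f"{n} epochs cannot support {max(grid.N_range)} clusters")
    prefix = _prefix_sums(X)
    results: dict[tuple[int, int, int], np.ndarray] = {}
    for K in grid.K_range:
        children = ward_tree(X, connectivity=_band_connectivity(n, min(K, n)))[0]
        for N in grid.N_range:
            try:
                labels = _cut_ward_tree(children, n, N)
                base = clusters_to_segments(labels)
                for L in grid.L_values:
                    p = merge_short_segments(base, X, L, _prefix=prefix)
                    p = merge_close_segments(p, X, grid.W, _prefix=prefix)
                    results[(N, K, L)] = p.interior
            except Exception as err:  # propagate with triple identity
                raise RuntimeError(f"phase 1 failed at (N={N}, K={K})") from err
    return results


# ---------------------------------------------------------------------------
# phase 2: pool candidates, cluster them, select the final boundaries


def build_joint_candidates(
    results: dict[tuple[int, int, int], np.ndarray], N_max: int, K_max: int, L: int
) -> np.ndarray:
    """Multiset union of candidates over triples with N <= N_max, K <= K_max
    at fixed L, sorted ascending with duplicates preserved (multiplicity
    measures a boundary's stability across the ensemble)."""
    arrays = [v for (N, K, Lv), v in results.items() if N <= N_max and K <= K_max and Lv == L]
    if not arrays:
        raise ValueError(f"no phase-1 triples with N <= {N_max}, K <= {K_max}, L = {L}")
    joined = np.concatenate(arrays) if arrays else np.array([], dtype=np.int64)
    return np.sort(joined).astype(np.int64)


def _center(values: np.ndarray, center_type: str) -> int:
    """Integer cluster center; mean/median round half-up, mode ties -> smallest."""
    if center_type == "mean":
        return int(np.floor(values.mean() + 0.5))
    if center_type == "median":
        return int(np.floor(np.median(values) + 0.5))
    if center_type == "mode":
        uniq, counts = np.unique(values, return_counts=True)
        return int(uniq[np.argmax(counts)])  # first max = smallest value
    raise ValueError(f"unknown center type {center_type!r}")


def cluster_candidates(
    candidates: np.ndarray,
    method: str,
    param,
    center_type: str,
    n_epochs: int,
    *,
    random_state=0,
    min_samples: int = 5,
) -> np.ndarray:
    """Cluster the 1-D boundary-candidate multiset and emit integer centers.

    KMeans keeps duplicates (implicit frequency weighting, k-means++ init,
    10 restarts, seeded).  DBSCAN runs on indices normalized by the epoch
    count so its radius is scale-free; noise points are dropped.  Returns
    the sorted, deduplicated centers inside (0, n_epochs); empty when the
    clustering yields no clusters.
    """
    candidates = np.asarray(candidates, dtype=np.float64)
    labels = _cluster_labels(candidates, method, param, n_epochs, random_state=random_state, min_samples=min_samples)
    if labels is None:
        return np.array([], dtype=np.int64)
    return _centers_from_labels(candidates, labels, center_type, n_epochs)


def _cluster_labels(candidates, method, param, n_epochs, *, random_state=0, min_samples=5):
    candidates = np.asarray(candidates, dtype=np.float64)
    if method == "kmeans":
        k = int(param)
        if len(np.unique(candidates)) < k:
            return None  # cannot form k distinct boundary clusters
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        return km.fit_predict(candidates.reshape(-1, 1))
    if method == "dbscan":
        labels = DBSCAN(eps=float(param), min_samples=min_samples).fit_predict(
            (candidates / n_epochs).reshape(-1, 1)
        )
        return labels if (labels != -1).any() else None
    raise ValueError(f"unknown method {method!r}")


def _centers_from_labels(candidates, labels, center_type, n_epochs):
    candidates = np.asarray(candidates, dtype=np.float64)
    centers = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        centers.append(_center(candidates[labels == lab], center_type))
    centers = sorted({c for c in centers if 0 < c < n_epochs})
    return np.array(centers, dtype=np.int64)


def select_partition(X: np.ndarray, candidate_lists, n_interior: int):
    """Among candidate boundary lists with exactly ``n_interior`` interior
    boundaries, return (winning partition, its scores, winning config).

    ``candidate_lists`` is an iterable of (config, interior ndarray) in the
    canonical enumeration order; ties in the state-adapted silhouette go to
    the earliest configuration.  Returns None when no list qualifies.
    """
    n = X.shape[0]
    best = None
    cache: dict[bytes, float] = {}
    for config, interior in candidate_lists:
        if len(interior) != n_interior:
            continue
        key = np.asarray(interior).tobytes()
        if key not in cache:
            partition = SegmentPartition.from_interior(interior, n)
            cache[key] = state_adapted_silhouette(X, partition)
        sil = cache[key]
        if best is None or sil > best[0]:
            best = (sil, SegmentPartition.from_interior(interior, n), config)
    if best is None:
        return None
    sil, partition, config = best
    return partition, state_adapted_scores(X, partition), config


# ---------------------------------------------------------------------------
# the estimator


class StateDetector(BaseEstimator):
    """Ensemble change-point detector over a preprocessed epoch matrix.

    Parameters
    ----------
    grid : SDAHyperGrid, optional
        The hyperparameter ensemble (study defaults when omitted).
    random_state : int or RandomState
        Seeds the KMeans candidate clustering.

    Attributes (after ``fit``)
    --------------------------
    partitions_ : dict[int, SegmentPartition]
        Best partition per number of states (N_KM + 1).
    scores_ : dict[int, StateAdaptedScores]
        The five state-adapted quality measures for each winner.
    configs_ : dict[int, tuple]
        The winning phase-2 configuration per state count.
    phase1_results_ : dict[(N, K, L), ndarray]
        Interior boundary candidates per phase-1 triple.
    joint_candidates_ : dict[(L, N_max, K_max), ndarray]
        Pooled candidate multisets (exportable for stability scatter plots).

    The detector deliberately does not auto-select a single number of
    states: that choice is an expert decision made from the reported
    quality measures.
    """

    def __init__(self, grid: SDAHyperGrid | None = None, random_state=0):
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y=None) -> "StateDetector":
        grid = self.grid or SDAHyperGrid()
        X = check_array(X)
        n = X.shape[0]
        if n < min(grid.K_range):
            raise ValueError(f"{n} epochs is shorter than the smallest connectivity radius {min(grid.K_range)}")
        rng = check_random_state(self.random_state)
        seed = int(rng.randint(0, 2**31 - 1))

        self.phase1_results_ = phase1(X, grid)
        self.joint_candidates_ = {}
        candidate_lists: list[tuple[tuple, np.ndarray]] = []
        for L in grid.L_values:
            for N_max in grid.N_max_values:
                for K_max in grid.K_max_values:
                    joint = build_joint_candidates(self.phase1_results_, N_max, K_max, L)
                    self.joint_candidates_[(L, N_max, K_max)] = joint
                    if len(joint) == 0:
                        continue
                    for method, params in (("kmeans", grid.N_KM_range), ("dbscan", grid.E_DBS_values)):
                        for param in params:
                            labels = _cluster_labels(
                                joint, method, param, n,
                                random_state=seed, min_samples=grid.dbscan_min_samples,
                            )
                            if labels is None:
                                continue
                            for center_type in grid.center_types:
                                centers = _centers_from_labels(joint, labels, center_type, n)
                                if len(centers):
                                    candidate_lists.append(
                                        ((L, N_max, K_max, method, param, center_type), centers)
                                    )

        self.partitions_ = {}
        self.scores_ = {}
        self.configs_ = {}
        for n_km in grid.N_KM_range:
            chosen = select_partition(X, candidate_lists, n_km)
            if chosen is None:
                continue
            partition, scores, config = chosen
            n_states = n_km + 1
            self.partitions_[n_states] = partition
            self.scores_[n_states] = scores
            self.configs_[n_states] = config
        self.n_epochs_ = n
        return self

    def report(self) -> dict:
        """JSON-serializable quality report over all state counts."""
        return {
            int(k): {
                "boundaries": self.partitions_[k].boundaries.tolist(),
                "config": list(self.configs_[k]),
                "scores": self.scores_[k].as_dict(),
            }
            for k in sorted(self.partitions_)
        }


def run_sda(X, grid: SDAHyperGrid | None = None, random_state=0) -> dict[int, tuple[SegmentPartition, dict]]:
    """Full pipeline on a preprocessed epoch matrix.

    Returns a map n_states -> (partition, quality report).  The matrix is
    expected to be the reduced (epochs x components) detector input.
    """
    det = StateDetector(grid=grid, random_state=random_state).fit(X)
    return {
        k: (det.partitions_[k], {"config": det.configs_[k], "scores": det.scores_[k].as_dict()})
        for k in sorted(det.partitions_)
    }
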