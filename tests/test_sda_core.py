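import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from statedetect import SDAHyperGrid, SegmentPartition, StateDetector
from statedetect.sda_core import (
    ClusterSummary,
    build_joint_candidates,
    centroid_distance,
    cluster_candidates,
    clusters_to_segments,
    merge_close_segments,
    merge_short_segments,
    phase1,
    select_partition,
    ward_connectivity_cluster,
    ward_distance,
)


def brute_ward_connectivity(X, N, K):
    """Reference agglomeration: greedy smallest-Ward merge among clusters
    connected by at least one |i-j| <= K edge."""
    X = np.atleast_2d(X.astype(float))
    clusters = [{i} for i in range(len(X))]
    while len(clusters) > N:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if not any(abs(i - j) <= K for i in clusters[a] for j in clusters[b]):
                    continue
                ca = X[list(clusters[a])]
                cb = X[list(clusters[b])]
                na, nb = len(ca), len(cb)
                diff = ca.mean(axis=0) - cb.mean(axis=0)
                d = na * nb / (na + nb) * diff @ diff
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    labels = np.empty(len(X), dtype=int)
    for lab, members in enumerate(clusters):
        for i in members:
            labels[i] = lab
    return labels


def _same_partition(l1, l2):
    """Two labelings define the same set partition."""
    m1 = {}
    m2 = {}
    for a, b in zip(l1, l2):
        if m1.setdefault(a, b) != b or m2.setdefault(b, a) != a:
            return False
    return True


class TestWardDistances:
    def test_identical_singletons(self):
        a = ClusterSummary.from_points([[1.0, 1.0]])
        assert ward_distance(a, a) == 0.0

    def test_singletons_1d(self):
        a = ClusterSummary.from_points([[0.0]])
        b = ClusterSummary.from_points([[2.0]])
        assert ward_distance(a, b) == pytest.approx(2.0)

    def test_pairs_1d(self):
        a = ClusterSummary.from_points([[0.0], [2.0]])
        b = ClusterSummary.from_points([[6.0], [8.0]])
        assert ward_distance(a, b) == pytest.approx(36.0)
        assert centroid_distance(a, b) == pytest.approx(6.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = ClusterSummary.from_points(rng.normal(size=(4, 3)))
        b = ClusterSummary.from_points(rng.normal(size=(7, 3)))
        assert ward_distance(a, b) == ward_distance(b, a)


class TestWardConnectivityCluster:
    def test_two_blobs_split_at_change_point(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(5, 0.3, 50)]).reshape(-1, 1)
        labels = ward_connectivity_cluster(X, N=2, K=20)
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 2)).astype(np.float64)
        for N, K in [(3, 5), (4, 8), (2, 3)]:
            ours = ward_connectivity_cluster(X, N, K)
            ref = brute_ward_connectivity(X, N, K)
            assert _same_partition(ours, ref)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_unconstrained_limit_equals_scipy_ward(self, seed):
        # K >= n makes the constraint vacuous; compare against scipy's
        # unconstrained Ward linkage on up-to-200-point instances.
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 4))
        Z = linkage(X, method="ward")
        for N in (2, 5, 9):
            ours = ward_connectivity_cluster(X, N, K=len(X))
            ref = fcluster(Z, t=N, criterion="maxclust")
            assert _same_partition(ours, ref)

    def test_each_epoch_own_cluster(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        labels = ward_connectivity_cluster(X, N=6, K=2)
        assert len(set(labels)) == 6

    def test_too_many_clusters(self):
        with pytest.raises(ValueError, match="cannot form"):
            ward_connectivity_cluster(np.zeros((3, 1)), N=5, K=2)


class TestClustersToSegments:
    def test_contiguous_labels(self):
        p = clusters_to_segments([0, 0, 1, 1, 0, 0])
        assert p.boundaries.tolist() == [0, 2, 4, 6]

    def test_time_contiguous_clusters_coincide(self):
        p = clusters_to_segments([0, 0, 0, 1, 1, 2, 2, 2])
        assert p.segments == [(0, 3), (3, 5), (5, 8)]

    def test_interleaved_finer_tiling(self):
        p = clusters_to_segments([0, 1, 0, 1])
        # cluster 0 spans [0,3), cluster 1 spans [1,4)
        assert p.boundaries.tolist() == [0, 1, 3, 4]


class TestMergeShortSegments:
    def test_L0_noop(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        p = SegmentPartition([0, 3, 10])
        assert merge_short_segments(p, X, 0) == p

    def test_merges_into_ward_nearest_side(self):
        # middle segment [3,4) is closer (Ward) to the left block
        X = np.array([[0.0]] * 3 + [[0.5]] + [[10.0]] * 6)
        p = SegmentPartition([0, 3, 4, 10])
        out = merge_short_segments(p, X, L=1)
        assert out.boundaries.tolist() == [0, 4, 10]

    def test_all_short_collapses_to_one(self):
        X = np.random.default_rng(1).normal(size=(9, 1))
        p = SegmentPartition([0, 3, 6, 9])
        out = merge_short_segments(p, X, L=10)
        assert out.n_states == 1

    def test_result_has_no_short_segments(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        p = SegmentPartition([0, 2, 5, 11, 30, 33, 50])
        out = merge_short_segments(p, X, L=5)
        assert (out.durations > 5).all() or out.n_states == 1


class TestMergeCloseSegments:
    def test_hand_iteration(self):
        # adjacent Ward distances {1, 10}: D_avg = 5.5, the 1-pair merges;
        # with two segments left D_min = D_avg, so 0.3 stops the loop.
        X = np.concatenate([
            np.zeros(8), np.full(8, 0.5), np.full(8, 10.0)
        ]).reshape(-1, 1)
        p = SegmentPartition([0, 8, 16, 24])
        d01 = 8 * 8 / 16 * 0.5**2  # = 1
        d12 = 8 * 8 / 16 * 9.5**2
        assert d01 < 0.3 * np.mean([d01, d12])
        out = merge_close_segments(p, X, W=0.3)
        assert out.boundaries.tolist() == [0, 16, 24]

    def test_two_segments_never_merge_below_W1(self):
        X = np.concatenate([np.zeros(5), np.ones(5)]).reshape(-1, 1)
        p = SegmentPartition([0, 5, 10])
        assert merge_close_segments(p, X, W=0.3) == p

    def test_equal_distances_no_merge(self):
        X = np.concatenate([np.zeros(4), np.full(4, 1.0), np.full(4, 2.0)]).reshape(-1, 1)
        p = SegmentPartition([0, 4, 8, 12])
        out = merge_close_segments(p, X, W=0.5)
        assert out == p

    def test_termination_and_postcondition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        p = SegmentPartition([0, 5, 12, 20, 31, 45, 60])
        out = merge_close_segments(p, X, W=0.3)
        if out.n_states >= 2:
            from statedetect.sda_core import _adjacent_ward, _prefix_sums

            d = _adjacent_ward(_prefix_sums(X), out.boundaries)
            assert d.min() > 0.3 * d.mean() or len(d) == 1


class TestPhase1:
    def test_candidate_count_matches_grid(self):
        grid = SDAHyperGrid(
            N_range=(2, 3), K_range=(20, 21), L_values=(0, 20),
            N_max_values=(2,), K_max_values=(21,), N_KM_range=(2,),
        )
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        results = phase1(X, grid)
        assert len(results) == 2 * 2 * 2 == grid.n_phase1_triples

    def test_planted_boundary_within_K(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (60, 2)), rng.normal(3, 0.2, (60, 2))])
        grid = SDAHyperGrid(
            N_range=(2, 3), K_range=(20, 30), L_values=(0,),
            N_max_values=(3,), K_max_values=(30,), N_KM_range=(2,),
        )
        for (N, K, L), cand in phase1(X, grid).items():
            assert all(abs(c - 60) <= K for c in cand)


class TestJointCandidates:
    def test_multiset_union(self):
        results = {(2, 20, 0): np.array([10, 50]), (3, 20, 0): np.array([12, 50])}
        joint = build_joint_candidates(results, N_max=3, K_max=20, L=0)
        assert joint.tolist() == [10, 12, 50, 50]

    def test_single_triple_identity(self):
        results = {(2, 20, 0): np.array([7, 30])}
        joint = build_joint_candidates(results, N_max=2, K_max=20, L=0)
        assert joint.tolist() == [7, 30]

    def test_multiplicity_equals_contributing_triples(self):
        rng = np.random.default_rng(6)
        results = {
            (N, K, 0): np.array([40]) if rng.random() < 0.7 else np.array([40, 80])
            for N in (2, 3, 4) for K in (20, 21)
        }
        joint = build_joint_candidates(results, N_max=4, K_max=21, L=0)
        count_40 = sum(1 for v in results.values() if 40 in v)
        assert (joint == 40).sum() == count_40

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="no phase-1 triples"):
            build_joint_candidates({(5, 20, 0): np.array([1])}, N_max=3, K_max=20, L=40)


class TestClusterCandidates:
    def test_kmeans_mode_tiebreak_smallest(self):
        cand = np.array([10, 12, 50, 50])
        centers = cluster_candidates(cand, "kmeans", 2, "mode", n_epochs=100)
        assert centers.tolist() == [10, 50]

    def test_kmeans_mean_centers(self):
        cand = np.array([10, 12, 50, 50])
        centers = cluster_candidates(cand, "kmeans", 2, "mean", n_epochs=100)
        assert centers.tolist() == [11, 50]

    def test_identical_candidates_single_center(self):
        cand = np.array([33, 33, 33, 33, 33])
        for ct in ("mean", "median", "mode"):
            centers = cluster_candidates(cand, "dbscan", 0.02, ct, n_epochs=100)
            assert centers.tolist() == [33]

    def test_dbscan_no_clusters_empty(self):
        cand = np.array([10, 40, 70])  # all noise at min_samples=5
        centers = cluster_candidates(cand, "dbscan", 0.01, "mean", n_epochs=100)
        assert len(centers) == 0

    def test_boundaries_at_edges_dropped(self):
        cand = np.array([0] * 6 + [50] * 6)
        centers = cluster_candidates(cand, "dbscan", 0.02, "mean", n_epochs=100)
        assert centers.tolist() == [50]


class TestSelectPartition:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(4, 0.3, (40, 2))])
        out = select_partition(X, [(("cfg",), np.array([40]))], 1)
        assert out is not None
        partition, scores, config = out
        assert partition.boundaries.tolist() == [0, 40, 80]

    def test_true_boundaries_beat_shifted(self):
        rng = np.random.default_rng(8)
        X = np.vstack([
            rng.normal(0, 0.3, (60, 2)),
            rng.normal(4, 0.3, (60, 2)),
            rng.normal(8, 0.3, (60, 2)),
        ])
        lists = [
            (("shifted",), np.array([30, 90])),
            (("true",), np.array([60, 120])),
        ]
        partition, scores, config = select_partition(X, lists, 2)
        assert config == ("true",)
        assert partition.interior.tolist() == [60, 120]

    def test_tie_goes_to_first_config(self):
        X = np.random.default_rng(9).normal(size=(50, 2))
        lists = [(("first",), np.array([25])), (("second",), np.array([25]))]
        _, _, config = select_partition(X, lists, 1)
        assert config == ("first",)

    def test_wrong_count_excluded(self):
        X = np.random.default_rng(10).normal(size=(50, 2))
        assert select_partition(X, [(("a",), np.array([10, 20]))], 1) is None


class TestStateDetector:
    def _planted(self, seed=11):
        rng = np.random.default_rng(seed)
        return np.vstack([
            rng.normal(0, 0.5, (70, 4)),
            rng.normal(3, 0.5, (90, 4)),
            rng.normal(-3, 0.5, (80, 4)),
        ])

    def test_recovers_planted_boundaries(self):
        X = self._planted()
        grid = SDAHyperGrid.small()
        det = StateDetector(grid=grid, random_state=0).fit(X)
        assert 3 in det.partitions_
        np.testing.assert_allclose(det.partitions_[3].interior, [70, 160], atol=3)

    def test_partitions_tile_epoch_axis(self):
        X = self._planted(seed=12)
        det = StateDetector(grid=SDAHyperGrid.small(), random_state=0).fit(X)
        for p in det.partitions_.values():
            assert p.boundaries[0] == 0 and p.boundaries[-1] == len(X)
            assert (p.durations > 0).all()

    def test_deterministic_under_fixed_seed(self):
        X = self._planted(seed=13)
        d1 = StateDetector(grid=SDAHyperGrid.small(), random_state=42).fit(X)
        d2 = StateDetector(grid=SDAHyperGrid.small(), random_state=42).fit(X)
        assert sorted(d1.partitions_) == sorted(d2.partitions_)
        for k in d1.partitions_:
            assert d1.partitions_[k] == d2.partitions_[k]

    def test_too_short_recording_rejected(self):
        X = np.random.default_rng(0).normal(size=(15, 3))
        with pytest.raises(ValueError, match="shorter than"):
            StateDetector(grid=SDAHyperGrid.small()).fit(X)


class TestHyperGrid:
    def test_default_triple_count(self):
        assert SDAHyperGrid().n_phase1_triples == 19 * 31 * 4 == 2356

    def test_invalid_W(self):
        with pytest.raises(ValueError, match="W"):
            SDAHyperGrid(W=1.5)

    def test_nmax_must_fit_range(self):
        with pytest.raises(ValueError, match="N_max"):
            SDAHyperGrid(N_range=(2, 3), N_max_values=(10,))
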