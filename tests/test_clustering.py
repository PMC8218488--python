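"""Density clustering, QT-RMSD reference clustering, cluster-size series."""

import numpy as np
import pytest

from castelo.clustering import (
    ClusterAssignment,
    ClusterSizeSeries,
    _qt_cluster_from_matrix,
    cluster_latent,
    is_stable,
    pairwise_ligand_rmsd,
    qt_rmsd_cluster,
    size_series,
)
from castelo.contacts import load_trajectory
from castelo.exceptions import AlignmentError


def brute_force_qt(dist, cutoff):
    """Independent quality-threshold oracle with explicit python loops."""
    T = dist.shape[0]
    labels = [-1] * T
    remaining = set(range(T))
    label = 0
    while remaining:
        best_center, best_members = None, None
        for c in sorted(remaining):  # lowest index wins ties
            members = {j for j in remaining if dist[c, j] <= cutoff}
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        for j in best_members:
            labels[j] = label
        remaining -= best_members
        label += 1
    return labels


class TestClusterLatent:
    def test_two_planted_blobs_two_clusters(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0, 0.1, (100, 3)), rng.normal(10, 0.1, (100, 3))]
        )
        assign = cluster_latent(X, min_cluster_size=50)
        labels = assign.labels
        assert set(labels) == {0, 1}
        assert sorted(np.bincount(labels)) == [100, 100]
        # blob membership is coherent
        assert len(set(labels[:100])) == 1 and len(set(labels[100:])) == 1

    def test_fewer_points_than_minimum_all_noise(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        assert (cluster_latent(X, min_cluster_size=50).labels == -1).all()

    def test_identical_points_single_cluster(self):
        X = np.zeros((200, 3))
        labels = cluster_latent(X, min_cluster_size=50).labels
        assert (labels == 0).all()


class TestQTCluster:
    def test_identical_frames_one_cluster(self, one_state_traj):
        traj = load_trajectory(*one_state_traj)
        assign = qt_rmsd_cluster(traj, cutoff=2.0)
        assert (assign.labels == 0).all()

    def test_two_pose_trajectory_two_clusters(self, two_state_traj):
        traj = load_trajectory(*two_state_traj)
        assign = qt_rmsd_cluster(traj, cutoff=2.0)
        assert len(set(assign.labels)) == 2
        # poses alternate frame by frame
        assert len(set(assign.labels[::2])) == 1
        assert len(set(assign.labels[1::2])) == 1

    def test_tiny_cutoff_all_distinct_frames_singletons(self, rng):
        dist = rng.random((6, 6)) + 1.0
        np.fill_diagonal(dist, 0.0)
        assign = _qt_cluster_from_matrix(np.maximum(dist, dist.T), cutoff=0.0)
        assert sorted(assign.labels) == list(range(6))

    def test_max_cluster_cap_labels_leftovers_noise(self, rng):
        dist = np.full((6, 6), 10.0)
        np.fill_diagonal(dist, 0.0)
        assign = _qt_cluster_from_matrix(dist, cutoff=1.0, max_clusters=2)
        assert (assign.labels == -1).sum() == 4

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 9))
        pts = rng.random((T, 2)) * 3
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cutoff = float(rng.random() * 2)
        ours = _qt_cluster_from_matrix(dist, cutoff).labels.tolist()
        assert ours == brute_force_qt(dist, cutoff)

    def test_pairwise_rmsd_is_metric_like(self, two_state_traj):
        traj = load_trajectory(*two_state_traj)
        rmsd = pairwise_ligand_rmsd(traj)
        assert np.allclose(rmsd, rmsd.T)
        assert np.allclose(np.diag(rmsd), 0.0, atol=1e-10)
        # the two planted poses are far apart in ligand RMSD
        assert rmsd[0, 1] > 5.0


class TestSizeSeries:
    def test_counts_and_noise_rule(self):
        sizes = size_series(ClusterAssignment(labels=[0, 0, 1, -1])).sizes
        assert sizes.tolist() == [2, 2, 1, 1]

    def test_single_cluster(self):
        sizes = size_series(ClusterAssignment(labels=[0] * 10)).sizes
        assert sizes.tolist() == [10] * 10

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(-1, 4, size=50)
        perm = {-1: -1, 0: 3, 1: 0, 2: 1, 3: 2}
        relabeled = np.array([perm[int(x)] for x in labels])
        a = size_series(ClusterAssignment(labels=labels)).sizes
        b = size_series(ClusterAssignment(labels=relabeled)).sizes
        assert np.array_equal(a, b)

    def test_distinct_sizes_plus_noise_covers_all_frames(self, rng):
        labels = rng.integers(-1, 5, size=200)
        assign = ClusterAssignment(labels=labels)
        sizes = size_series(assign).sizes
        uniq = set(labels[labels >= 0])
        total = sum((labels == u).sum() for u in uniq) + (labels == -1).sum()
        assert total == 200
        for u in uniq:  # frames of one cluster share one size
            assert len(set(sizes[labels == u])) == 1


class TestIsStable:
    def test_exactly_fifty_ns_is_not_stable(self):
        series = ClusterSizeSeries(sizes=np.full(2500, 2500))
        assert not is_stable(series, frame_interval_ps=20.0)

    def test_longer_than_fifty_ns_is_stable(self):
        series = ClusterSizeSeries(sizes=np.full(3000, 3000))
        assert is_stable(series, frame_interval_ps=20.0)

    def test_all_singletons_never_stable(self):
        series = ClusterSizeSeries(sizes=np.ones(5000, dtype=int))
        assert not is_stable(series, frame_interval_ps=20.0)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            is_stable(ClusterSizeSeries(sizes=np.ones(3, dtype=int)), 0.0)


def test_assignment_csv_roundtrip(tmp_path):
    assign = ClusterAssignment(labels=[0, 1, -1, 0], source="external")
    path = tmp_path / "assign.csv"
    assign.to_csv(path)
    back = ClusterAssignment.from_csv(path)
    assert np.array_equal(back.labels, assign.labels)


def test_assignment_csv_must_cover_frames(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("frame,label\n0,0\n2,1\n")
    with pytest.raises(AlignmentError):
        ClusterAssignment.from_csv(path)
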