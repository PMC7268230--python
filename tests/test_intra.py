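"""Stage-1 clustering: point labels, grouping, reassignment, merging."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from swmlabel.geometry import mdf_distance, mean_fiber
from swmlabel.intra import (ClusteringParams, cluster_points,
                            cluster_tractogram, compute_centroid,
                            merge_close_clusters, preliminary_clusters,
                            reassign_small_clusters)

from conftest import straight_fiber


def planted_fibers(rng, n_bundles=10, n_per=50, sigma=0.5, sep=20.0):
    """Well-separated straight planted bundles with jitter; returns
    (stacked resampled fibers, ground-truth labels)."""
    fibers, truth = [], []
    for b in range(n_bundles):
        base = straight_fiber([0, b * sep, 0], [45, b * sep, 10])
        for _ in range(n_per):
            f = base + rng.normal(scale=sigma, size=base.shape)
            if rng.random() < 0.5:
                f = f[::-1]
            fibers.append(f)
            truth.append(b)
    return np.stack(fibers), np.array(truth)


class TestClusterPoints:
    def test_two_separated_blobs(self, rng):
        a = straight_fiber([0, 0, 0], [40, 0, 0])
        b = straight_fiber([0, 50, 0], [40, 50, 0])
        fibers = np.stack([a + rng.normal(scale=0.2, size=a.shape)
                           for _ in range(20)]
                          + [b + rng.normal(scale=0.2, size=b.shape)
                             for _ in range(20)])
        labels = cluster_points(fibers, ClusteringParams(k_points=2, random_seed=3))
        for col in labels.T:
            assert len(set(col[:20])) == 1
            assert len(set(col[20:])) == 1
            assert col[0] != col[20]

    def test_single_fiber(self):
        fibers = straight_fiber([0, 0, 0], [40, 0, 0])[None]
        labels = cluster_points(fibers, ClusteringParams(k_points=5, random_seed=0))
        assert labels.shape == (1, 5)

    def test_seed_determinism(self, rng):
        fibers, _ = planted_fibers(rng, n_bundles=3, n_per=10)
        p = ClusteringParams(k_points=6, random_seed=11)
        np.testing.assert_array_equal(cluster_points(fibers, p),
                                      cluster_points(fibers, p))


class TestPreliminary:
    def test_identical_tuples_group(self):
        labels = np.array([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        groups = preliminary_clusters(labels)
        assert len(groups) == 1

    def test_reversed_tuple_groups_flipped_storage(self):
        labels = np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        assert len(preliminary_clusters(labels)) == 1

    def test_one_position_differs(self):
        labels = np.array([[1, 2, 3, 4, 5], [1, 2, 9, 4, 5]])
        assert len(preliminary_clusters(labels)) == 2


class TestReassign:
    def test_small_group_absorbed_under_threshold(self, rng):
        big = np.stack([straight_fiber([0, 0, 0], [40, 0, 0])
                        + rng.normal(scale=0.1, size=(21, 3))
                        for _ in range(50)])
        lone = straight_fiber([0, 2, 0], [40, 2, 0])[None]
        resampled = np.concatenate([big, lone])
        groups = {(1, 1, 1, 1, 1): np.arange(50), (2, 2, 2, 2, 2): np.array([50])}
        out = reassign_small_clusters(groups, resampled, 6.0, 3)
        assert len(out) == 1
        assert len(out[0][1]) == 51

    def test_distant_small_group_kept(self, rng):
        big = np.stack([straight_fiber([0, 0, 0], [40, 0, 0])
                        for _ in range(50)])
        lone = straight_fiber([0, 30, 0], [40, 30, 0])[None]
        resampled = np.concatenate([big, lone])
        groups = {(1,) * 5: np.arange(50), (2,) * 5: np.array([50])}
        out = reassign_small_clusters(groups, resampled, 6.0, 3)
        assert len(out) == 2

    def test_matches_bruteforce_nearest_large(self, rng):
        # 20 random groups of mixed size; verify each small group's fate
        resampled, groups, start = [], {}, 0
        for g in range(20):
            n = int(rng.integers(1, 6))
            base = straight_fiber(rng.uniform(0, 80, 3),
                                  rng.uniform(0, 80, 3) + [40, 0, 0])
            for _ in range(n):
                resampled.append(base + rng.normal(scale=0.3, size=(21, 3)))
            groups[(g,) * 5] = np.arange(start, start + n)
            start += n
        resampled = np.stack(resampled)
        thr, min_size = 6.0, 3
        out = reassign_small_clusters(groups, resampled, thr, min_size)

        cents = {k: mean_fiber(resampled[v]) for k, v in groups.items()}
        large = [k for k, v in groups.items() if len(v) >= min_size]
        expected_members = {k: set(groups[k]) for k in large}
        kept_small = []
        for k, v in groups.items():
            if len(v) >= min_size:
                continue
            dists = [(mdf_distance(cents[k], cents[kl]), kl) for kl in large]
            if large and min(dists)[0] <= thr:
                expected_members[min(dists)[1]] |= set(v)
            else:
                kept_small.append(set(v))
        got = sorted([set(idx) for _, idx, _ in out], key=min)
        exp = sorted(list(expected_members.values()) + kept_small, key=min)
        assert got == exp


class TestMerge:
    def base_candidates(self, rng, offset_y=3.0, central_same=True):
        a = np.stack([straight_fiber([0, 0, 0], [40, 0, 0])
                      + rng.normal(scale=0.1, size=(21, 3)) for _ in range(10)])
        b = np.stack([straight_fiber([0, offset_y, 0], [40, offset_y, 0])
                      + rng.normal(scale=0.1, size=(21, 3)) for _ in range(10)])
        resampled = np.concatenate([a, b])
        central_b = 7 if central_same else 9
        cands = [((1, 2, 7, 3, 4), np.arange(10), mean_fiber(a)),
                 ((5, 6, central_b, 8, 9), np.arange(10, 20), mean_fiber(b))]
        return cands, resampled

    def test_close_same_central_label_merged(self, rng):
        cands, resampled = self.base_candidates(rng)
        out = merge_close_clusters(cands, resampled, 8.0, (0, 5, 10, 15, 20))
        assert len(out) == 1
        assert out[0].n_fibers == 20

    def test_different_central_label_not_merged(self, rng):
        cands, resampled = self.base_candidates(rng, central_same=False)
        out = merge_close_clusters(cands, resampled, 8.0, (0, 5, 10, 15, 20))
        assert len(out) == 2

    def test_far_apart_not_merged(self, rng):
        cands, resampled = self.base_candidates(rng, offset_y=30.0)
        out = merge_close_clusters(cands, resampled, 8.0, (0, 5, 10, 15, 20))
        assert len(out) == 2

    def test_matches_union_find_oracle(self, rng):
        # random candidates; single-linkage over qualifying pairs
        cands, resampled = [], []
        subset = (0, 5, 10, 15, 20)
        for g in range(12):
            base = straight_fiber(rng.uniform(0, 40, 3),
                                  rng.uniform(0, 40, 3) + [40, 0, 0])
            members = np.stack([base + rng.normal(scale=0.2, size=(21, 3))
                                for _ in range(5)])
            idx = np.arange(g * 5, g * 5 + 5)
            resampled.append(members)
            central = int(rng.integers(0, 3))
            cands.append(((g, g, central, g, g), idx, mean_fiber(members)))
        resampled = np.concatenate(resampled)
        thr = 12.0
        out = merge_close_clusters(cands, resampled, thr, subset)

        import networkx as nx
        G = nx.Graph()
        G.add_nodes_from(range(12))
        for i in range(12):
            for j in range(i + 1, 12):
                if cands[i][0][2] == cands[j][0][2] and \
                   mdf_distance(cands[i][2], cands[j][2]) <= thr:
                    G.add_edge(i, j)
        comps = sorted([sorted(c) for c in nx.connected_components(G)])
        got = sorted([sorted({m // 5 for m in c.member_indices})
                      for c in out])
        assert got == comps


class TestCentroid:
    def test_identical_members(self, rng):
        f = rng.normal(size=(21, 3))
        np.testing.assert_allclose(compute_centroid(np.stack([f] * 5)), f)

    def test_symmetric_pair_midline(self):
        a = straight_fiber([0, 1, 0], [40, 1, 0])
        b = straight_fiber([0, -1, 0], [40, -1, 0])
        mid = compute_centroid(np.stack([a, b]))
        np.testing.assert_allclose(mid[:, 1], 0.0, atol=1e-12)

    def test_reversed_storage_invariance(self, rng):
        base = straight_fiber([0, 0, 0], [40, 5, 0])
        fibers = np.stack([base + rng.normal(scale=0.2, size=(21, 3))
                           for _ in range(8)])
        mixed = fibers.copy()
        mixed[1::2] = mixed[1::2, ::-1]
        np.testing.assert_allclose(compute_centroid(fibers),
                                   compute_centroid(mixed), atol=1e-9)


class TestFullStage:
    def test_partition_property(self, rng):
        fibers, _ = planted_fibers(rng, n_bundles=5, n_per=20)
        cs = cluster_tractogram(fibers, ClusteringParams(k_points=15,
                                                         random_seed=2))
        all_idx = np.concatenate([c.member_indices for c in cs.clusters])
        assert sorted(all_idx) == list(range(len(fibers)))

    def test_determinism(self, rng):
        fibers, _ = planted_fibers(rng, n_bundles=4, n_per=15)
        p = ClusteringParams(k_points=12, random_seed=5)
        cs1 = cluster_tractogram(fibers, p)
        cs2 = cluster_tractogram(fibers, p)
        assert len(cs1) == len(cs2)
        for c1, c2 in zip(cs1.clusters, cs2.clusters):
            np.testing.assert_array_equal(c1.member_indices, c2.member_indices)
            np.testing.assert_allclose(c1.centroid, c2.centroid)

    def test_planted_structure_recovery(self, rng):
        fibers, truth = planted_fibers(rng, n_bundles=10, n_per=50,
                                       sigma=0.5, sep=20.0)
        cs = cluster_tractogram(fibers, ClusteringParams(random_seed=4))
        pred = np.empty(len(fibers), dtype=int)
        for c in cs.clusters:
            pred[c.member_indices] = c.cluster_id
        assert adjusted_rand_score(truth, pred) >= 0.99
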