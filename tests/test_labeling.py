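"""Stage-4 labeling: triangle votes, alignment, naming, positional order."""

import numpy as np
import pytest

from swmlabel.intersection import IntersectionRecord, build_grid, intersect_fiber
from swmlabel.io import LabeledMesh
from swmlabel.labeling import (align_cluster, assign_relative_indices,
                               name_bundle, triangle_label)

from conftest import straight_fiber


def mesh_with_labels(labels):
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    t = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    table = {int(l): f"R{l}" for l in set(labels)}
    return LabeledMesh(v, t, np.array(labels), table, "lh")


class TestTriangleLabel:
    def test_majority(self):
        mesh = mesh_with_labels([5, 5, 7, 7])
        assert triangle_label(mesh, 0) == 5      # (5,5,7)

    def test_unanimous(self):
        mesh = mesh_with_labels([4, 4, 4, 4])
        assert triangle_label(mesh, 0) == 4

    def test_three_way_tie_smallest_index(self):
        mesh = mesh_with_labels([3, 7, 9, 9])
        assert triangle_label(mesh, 0) == 3      # (3,7,9)


class TestAlign:
    def test_fiber_equal_to_centroid_unchanged(self):
        c = straight_fiber([0, 0, 0], [40, 0, 0])
        out, flip = align_cluster(c[None], c)
        assert not flip[0]
        np.testing.assert_array_equal(out[0], c)

    def test_reversed_fiber_flipped(self):
        c = straight_fiber([0, 0, 0], [40, 0, 0])
        out, flip = align_cluster(c[::-1][None], c)
        assert flip[0]
        np.testing.assert_array_equal(out[0], c)

    def test_postcondition_all_aligned(self, rng):
        c = straight_fiber([0, 0, 0], [40, 0, 0])
        fibers = np.stack([c + rng.normal(scale=1, size=(21, 3))
                           for _ in range(20)])
        fibers[::3] = fibers[::3, ::-1]
        out, _ = align_cluster(fibers, c)
        d1 = np.linalg.norm(out[:, 0] - c[0], axis=1)
        d2 = np.linalg.norm(out[:, 0] - c[-1], axis=1)
        assert np.all(d1 <= d2)


def records_for(labels_pairs, mesh):
    """Records whose start/end triangles have the requested region labels."""
    by_label = {}
    for t in range(len(mesh.triangles)):
        by_label.setdefault(triangle_label(mesh, t), t)
    recs = []
    for a, b in labels_pairs:
        recs.append(IntersectionRecord(
            tri_init=by_label[a], tri_end=by_label[b],
            point_init=np.zeros(3), point_end=np.ones(3),
            uv_init=(0.1, 0.1), uv_end=(0.1, 0.1)))
    return recs


class TestNameBundle:
    # region indices mimic the atlas: PoC=22, PrC=24
    def mesh(self):
        return mesh_with_labels([22, 22, 24, 24])

    def test_ordered_pair_kept(self):
        mesh = self.mesh()
        recs = records_for([(22, 24)] * 10, mesh)
        assert name_bundle(recs, mesh) == (22, 24, False)

    def test_inverted_pair_flagged_for_flip(self):
        mesh = self.mesh()
        recs = records_for([(24, 22)] * 10, mesh)
        assert name_bundle(recs, mesh) == (22, 24, True)

    def test_majority_vote_start(self):
        mesh = self.mesh()
        recs = records_for([(22, 24)] * 6 + [(24, 24)] * 4, mesh)
        assert name_bundle(recs, mesh)[0] == 22

    def test_no_voting_fibers_gives_none(self):
        mesh = self.mesh()
        assert name_bundle([IntersectionRecord()], mesh) is None


class TestRelativeIndices:
    def test_y_sorting(self):
        infos = [(np.array([0.0, 10, 0]), 5),
                 (np.array([0.0, -5, 0]), 5),
                 (np.array([0.0, 3, 0]), 5)]
        assert assign_relative_indices(infos) == [2, 0, 1]

    def test_single_bundle(self):
        assert assign_relative_indices([(np.zeros(3), 3)]) == [0]

    def test_tie_on_y_breaks_on_z(self):
        infos = [(np.array([0.0, 1, 2]), 5), (np.array([0.0, 1, 1]), 5)]
        assert assign_relative_indices(infos) == [1, 0]

    def test_descending_order(self):
        infos = [(np.array([0.0, 10, 0]), 5), (np.array([0.0, -5, 0]), 5)]
        assert assign_relative_indices(infos, ascending=False) == [0, 1]

    def test_x_axis(self):
        infos = [(np.array([7.0, 0, 0]), 5), (np.array([2.0, 0, 0]), 5)]
        assert assign_relative_indices(infos, axis="x") == [1, 0]


class TestPlantedNaming:
    def test_planted_bundles_named_by_their_parcels(self, sphere_mesh, rng):
        """Bundles planted between parcels A,B get the name A-B (atlas-index
        ordered) in >=99% of randomized trials at 1 mm jitter."""
        from swmlabel.geometry import resample_fibers
        from swmlabel.intra import FiberCluster, ClusterSet
        from swmlabel.labeling import label_clusters
        from swmlabel.synthetic import make_bundle, parcel_centers

        grid = build_grid(sphere_mesh)
        centers = parcel_centers(sphere_mesh)
        idxs = sorted(centers)
        trials = ok = 0
        for t in range(40):
            a, b = rng.choice(idxs, size=2, replace=False)
            ang = np.arccos(np.clip(centers[a] @ centers[b], -1, 1))
            if not 0.6 <= ang <= 1.1:
                continue
            lo, hi = sorted((int(a), int(b)))
            fibers, _ = make_bundle(sphere_mesh, lo, hi, 15, 1.0,
                                    seed=1000 + t)
            res = resample_fibers(fibers)
            cs = ClusterSet(
                clusters=[FiberCluster(0, np.arange(15),
                                       res.mean(axis=0))],
                resampled=res)
            recs = [intersect_fiber(f, sphere_mesh, grid) for f in res]
            bs = label_clusters(cs, recs, sphere_mesh, grid=grid)
            trials += 1
            if len(bs) == 1:
                lbl = bs.bundles[0].label
                expected = (sphere_mesh.region_table[lo],
                            sphere_mesh.region_table[hi])
                if (lbl.region_a, lbl.region_b) == expected:
                    ok += 1
        assert trials >= 10
        assert ok / trials >= 0.99

    def test_indices_contiguous_and_y_ordered(self, sphere_mesh, rng):
        from swmlabel.geometry import resample_fibers
        from swmlabel.intra import FiberCluster, ClusterSet
        from swmlabel.labeling import label_clusters
        from swmlabel.synthetic import make_bundle, parcel_centers

        grid = build_grid(sphere_mesh)
        centers = parcel_centers(sphere_mesh)
        # three bundles between the same parcel pair, shifted along the arc
        idxs = sorted(centers)
        pair = None
        for a in idxs:
            for b in idxs:
                if a < b and 0.7 <= np.arccos(
                        np.clip(centers[a] @ centers[b], -1, 1)) <= 1.0:
                    pair = (a, b)
                    break
            if pair:
                break
        a, b = pair
        all_fibers, clusters, start = [], [], 0
        rot = _small_rotations()
        for k in range(3):
            ua = rot[k] @ centers[a]
            ub = rot[k] @ centers[b]
            fibers, _ = make_bundle(sphere_mesh, a, b, 12, 0.5, seed=k,
                                    anchors=(ua, ub))
            all_fibers.extend(fibers)
            clusters.append(np.arange(start, start + 12))
            start += 12
        res = resample_fibers(all_fibers)
        cs = ClusterSet(clusters=[FiberCluster(i, idx, res[idx].mean(axis=0))
                                  for i, idx in enumerate(clusters)],
                        resampled=res)
        recs = [intersect_fiber(f, sphere_mesh, grid) for f in res]
        bs = label_clusters(cs, recs, sphere_mesh, grid=grid)
        same_pair = [bb for bb in bs.bundles
                     if (bb.label.region_a, bb.label.region_b)
                     == (sphere_mesh.region_table[a], sphere_mesh.region_table[b])]
        ks = sorted(bb.label.position_index for bb in same_pair)
        assert ks == list(range(len(same_pair)))
        ordered = sorted(same_pair, key=lambda bb: bb.label.position_index)
        ys = [bb.point_init[1] for bb in ordered]
        assert ys == sorted(ys)


def _small_rotations():
    """Three small rotations about z used to separate same-pair bundles."""
    out = []
    for ang in (-0.18, 0.0, 0.18):
        c, s = np.cos(ang), np.sin(ang)
        out.append(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]))
    return out
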