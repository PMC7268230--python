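"""Stage 4: cluster labeling from cortical connectivity.

Each surviving cluster is named after the two cortical regions its fibers
most often reach:

* a triangle's region is the most repeated label among its three vertex
  labels (ties to the smallest region index);
* fibers are first aligned to the cluster centroid — a fiber whose first
  point is closer to the centroid's last point than to its first is flipped,
  so "start" and "end" mean the same thing for every member;
* the most common label (mcl) over the aligned fibers' start triangles and,
  separately, end triangles names the bundle ``mcl_init-mcl_end``;
* the pair is put in ascending atlas-index order (PoC has index 22, PrC 24,
  so both PoC-PrC and PrC-PoC bundles end up named PoC-PrC, the latter with
  all fibers flipped);
* bundles sharing a region pair get a relative position index from sorting
  their centroids' intersection points in the first-named region along a
  spatial axis (default: ascending y, i.e. from the bottom up).

Only fibers with both extremities intersecting the mesh vote; a bundle with
no such fiber is left unlabeled and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import flip_fiber, mean_fiber
from .intersection import IntersectionRecord, build_grid, intersect_fiber
from .io import LabeledMesh


@dataclass(frozen=True)
class BundleLabel:
    """``<hemi>_<RegionA>-<RegionB>_<k>`` with regions in atlas-index order."""

    hemisphere: str
    region_a: str
    region_b: str
    position_index: int

    def render(self) -> str:
        return f"{self.hemisphere}_{self.region_a}-{self.region_b}_{self.position_index}"

    @property
    def region_pair(self) -> str:
        return f"{self.region_a}-{self.region_b}"


@dataclass
class LabeledBundle:
    """A named bundle: aligned member fibers plus centroid and anchor point."""

    label: BundleLabel
    fiber_indices: np.ndarray        # indices into the source tractogram
    fibers: np.ndarray               # (n, 21, 3), aligned
    centroid: np.ndarray             # (21, 3), same orientation as fibers
    point_init: np.ndarray           # centroid's intersection point in region_a

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_indices)


@dataclass
class LabeledBundleSet:
    subject_id: str
    bundles: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bundles)


def triangle_label(mesh: LabeledMesh, tri: int) -> int:
    """Most repeated region label among a triangle's three vertices;
    ties broken by the smallest region index."""
    labels = mesh.vertex_labels[mesh.triangles[tri]]
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[counts == counts.max()].min())


def align_cluster(fibers: np.ndarray, centroid: np.ndarray) -> tuple:
    """Orient every fiber like the centroid.

    Fiber i is flipped iff the Euclidean distance from its first point to the
    centroid's first point exceeds the distance to the centroid's last point
    (equality leaves it unchanged).  Returns (aligned fibers, flip mask).
    """
    fibers = np.asarray(fibers, dtype=float)
    d_first = np.linalg.norm(fibers[:, 0] - centroid[0], axis=1)
    d_last = np.linalg.norm(fibers[:, 0] - centroid[-1], axis=1)
    flip = d_first > d_last
    out = fibers.copy()
    out[flip] = out[flip, ::-1]
    return out, flip


def _mode_label(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[counts == counts.max()].min())


def name_bundle(aligned_records: list, mesh: LabeledMesh) -> tuple | None:
    """Region pair from majority votes over start and end triangles.

    ``aligned_records`` are per-fiber :class:`IntersectionRecord` objects in
    the aligned orientation.  Returns ``(mcl_init, mcl_end, needs_flip)``
    region indices, with ``needs_flip`` true when the pair had to be inverted
    to reach ascending atlas-index order; ``None`` if no fiber has both
    extremities intersecting.
    """
    voting = [r for r in aligned_records if r.both]
    if not voting:
        return None
    init = _mode_label(np.array([triangle_label(mesh, r.tri_init) for r in voting]))
    end = _mode_label(np.array([triangle_label(mesh, r.tri_end) for r in voting]))
    if init > end:
        return end, init, True
    return init, end, False


_AXIS_CYCLE = {"x": (0, 1, 2), "y": (1, 2, 0), "z": (2, 0, 1)}


def assign_relative_indices(bundle_infos: list, axis: str = "y",
                            ascending: bool = True) -> list:
    """Order bundles sharing a region pair along a spatial axis.

    ``bundle_infos`` is a list of ``(point_init, n_fibers)``; returns the
    position index of each entry.  Primary key: the chosen coordinate of the
    centroid's intersection point in the first-named region; ties fall to the
    next coordinates cyclically, then to fiber count (larger first).
    """
    order_axes = _AXIS_CYCLE[axis]
    sign = 1.0 if ascending else -1.0

    def key(item):
        i, (p, nf) = item
        return (sign * p[order_axes[0]], p[order_axes[1]], p[order_axes[2]], -nf, i)

    ranked = sorted(enumerate(bundle_infos), key=key)
    out = [0] * len(bundle_infos)
    for pos, (i, _) in enumerate(ranked):
        out[i] = pos
    return out


def label_clusters(cluster_set, records: list, mesh: LabeledMesh,
                   subject_id: str = "subject", axis: str = "y",
                   ascending: bool = True,
                   grid=None) -> LabeledBundleSet:
    """Name and index every cluster of one subject and hemisphere.

    ``records`` holds one :class:`IntersectionRecord` per tractogram fiber in
    its *stored* orientation; records of fibers flipped during alignment are
    swapped accordingly before voting.
    """
    if grid is None:
        grid = build_grid(mesh)

    named = []   # (region_a_idx, region_b_idx, indices, fibers, centroid, point_init)
    for cluster in cluster_set.clusters:
        members = cluster_set.resampled[cluster.member_indices]
        centroid = mean_fiber(members)
        aligned, flipmask = align_cluster(members, centroid)
        recs = [records[int(i)].flipped() if fl else records[int(i)]
                for i, fl in zip(cluster.member_indices, flipmask)]
        res = name_bundle(recs, mesh)
        if res is None:
            continue
        a_idx, b_idx, needs_flip = res
        if needs_flip:
            aligned = aligned[:, ::-1]
            centroid = flip_fiber(centroid)
        crec = intersect_fiber(centroid, mesh, grid)
        point_init = crec.point_init if crec.tri_init >= 0 else centroid[0].copy()
        named.append((a_idx, b_idx, cluster.member_indices, aligned,
                      centroid, point_init))

    bundles = []
    pairs = sorted({(a, b) for a, b, *_ in named})
    for a_idx, b_idx in pairs:
        group = [n for n in named if n[0] == a_idx and n[1] == b_idx]
        infos = [(n[5], len(n[2])) for n in group]
        positions = assign_relative_indices(infos, axis=axis, ascending=ascending)
        for n, k in zip(group, positions):
            label = BundleLabel(mesh.hemisphere, mesh.region_table[a_idx],
                                mesh.region_table[b_idx], k)
            bundles.append(LabeledBundle(label, n[2], n[3], n[4], n[5]))
    bundles.sort(key=lambda b: b.label.render())
    return LabeledBundleSet(subject_id=subject_id, bundles=bundles)
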