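"""Stage 1: whole-brain intra-subject fiber clustering.

A fast four-step scheme that scales to whole-brain tractograms:

1. mini-batch k-means is run independently on the 3D point clouds at a small
   subset of the 21 resampled positions (default {0, 5, 10, 15, 20}), giving
   each fiber one point-cluster label per position;
2. fibers sharing the full label tuple form preliminary clusters — a fiber
   stored in the opposite direction matches through its reversed tuple;
3. small preliminary clusters are reassigned to the nearest large cluster
   when the centroid MDF is under a threshold;
4. candidate clusters sharing the label at the central position are merged
   by single-linkage when centroid MDF is under a (larger) threshold.

Each final cluster carries a centroid: the pointwise mean of its
flip-aligned member fibers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import MiniBatchKMeans

from .geometry import K_POINTS, mdf_matrix, mean_fiber

#: Position of the central resampled point (index 10 of 0..20).
CENTRAL_POSITION = K_POINTS // 2


@dataclass
class ClusteringParams:
    """Tunable parameters for stage-1 clustering.

    ``k_points=None`` means the adaptive default ``min(200, n_fibers // 50)``
    (at least 2).  All distance thresholds are MDF in mm.
    """

    point_subset: tuple = (0, 5, 10, 15, 20)
    k_points: int | None = None
    reassign_threshold_mm: float = 6.0
    merge_threshold_mm: float = 8.0
    min_preliminary_size: int = 3
    batch_size: int = 1000
    random_seed: int = 0

    def __post_init__(self):
        if self.reassign_threshold_mm <= 0 or self.merge_threshold_mm <= 0:
            raise ValueError("thresholds must be positive")
        if any(p < 0 or p >= K_POINTS for p in self.point_subset):
            raise ValueError(f"point_subset must lie in [0, {K_POINTS})")

    def resolve_k(self, n_fibers: int) -> int:
        k = self.k_points if self.k_points is not None else min(200, n_fibers // 50)
        return max(1, min(max(k, 2), n_fibers))


@dataclass
class FiberCluster:
    """A cluster of similar fibers with a representative centroid."""

    cluster_id: int
    member_indices: np.ndarray          # indices into the tractogram
    centroid: np.ndarray                # (21, 3)
    label_tuple: tuple | None = None    # stage-1 point-cluster labels

    @property
    def n_fibers(self) -> int:
        return len(self.member_indices)


@dataclass
class ClusterSet:
    """All clusters of one subject plus the resampled fiber stack."""

    clusters: list
    resampled: np.ndarray               # (n_fibers, 21, 3)
    params: ClusteringParams | None = None

    def __len__(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# Step 1: point clustering
# ---------------------------------------------------------------------------

def cluster_points(resampled: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Mini-batch k-means on each subset position's 3D point cloud.

    Returns an ``(n_fibers, len(point_subset))`` integer label array.  The
    positions are clustered independently (they could run concurrently); with
    a fixed seed the result is reproducible regardless.
    """
    n = resampled.shape[0]
    k = params.resolve_k(n)
    if params.k_points is not None and params.k_points > n:
        warnings.warn(f"k_points={params.k_points} > {n} fibers; using k={k}")
    labels = np.empty((n, len(params.point_subset)), dtype=int)
    for j, pos in enumerate(params.point_subset):
        km = MiniBatchKMeans(
            n_clusters=k,
            batch_size=params.batch_size,
            max_iter=10,
            n_init=3,
            random_state=params.random_seed + pos,
        )
        labels[:, j] = km.fit_predict(resampled[:, pos, :])
    return labels


# ---------------------------------------------------------------------------
# Step 2: preliminary clusters
# ---------------------------------------------------------------------------

def preliminary_clusters(point_labels: np.ndarray) -> dict:
    """Group fibers sharing the full label tuple across subset positions.

    Storage direction is arbitrary, so a fiber also joins a group when its
    *reversed* tuple matches: each tuple is canonicalized to
    ``min(tuple, reversed(tuple))`` before grouping.  This requires the
    point subset to be symmetric about the fiber midpoint (the default is).
    """
    groups: dict = {}
    for i, row in enumerate(point_labels):
        tup = tuple(int(x) for x in row)
        canon = min(tup, tup[::-1])
        groups.setdefault(canon, []).append(i)
    return {k: np.array(v, dtype=int) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# Step 3: reassign small clusters
# ---------------------------------------------------------------------------

def reassign_small_clusters(groups: dict, resampled: np.ndarray,
                            reassign_threshold_mm: float,
                            min_preliminary_size: int) -> list:
    """Merge each small group into its nearest large group if the centroid
    MDF is at or under the threshold; otherwise keep it.

    Returns a list of ``(label_tuple, member_indices, centroid)`` triples.
    """
    items = sorted(groups.items())
    centroids = np.stack([mean_fiber(resampled[idx]) for _, idx in items]) \
        if items else np.empty((0, K_POINTS, 3))
    sizes = np.array([len(idx) for _, idx in items])
    large = np.flatnonzero(sizes >= min_preliminary_size)
    small = np.flatnonzero(sizes < min_preliminary_size)

    merged_members = {int(i): list(items[i][1]) for i in large}
    kept_small = []
    if large.size and small.size:
        dist = mdf_matrix(centroids[small], centroids[large])
        nearest = dist.argmin(axis=1)
        for row, si in enumerate(small):
            li = large[nearest[row]]
            if dist[row, nearest[row]] <= reassign_threshold_mm:
                merged_members[int(li)].extend(items[si][1])
            else:
                kept_small.append(si)
    else:
        kept_small = list(small)

    out = []
    for i in large:
        idx = np.array(sorted(merged_members[int(i)]), dtype=int)
        out.append((items[i][0], idx, mean_fiber(resampled[idx])))
    for i in kept_small:
        tup, idx = items[i]
        out.append((tup, np.asarray(idx, dtype=int), centroids[i]))
    return out


# ---------------------------------------------------------------------------
# Step 4: merge close clusters sharing the central label
# ---------------------------------------------------------------------------

def _central_label(label_tuple: tuple, point_subset: tuple) -> int | None:
    if CENTRAL_POSITION not in point_subset:
        return None
    return label_tuple[point_subset.index(CENTRAL_POSITION)]


def merge_close_clusters(candidates: list, resampled: np.ndarray,
                         merge_threshold_mm: float,
                         point_subset: tuple) -> list:
    """Single-linkage union of candidates sharing the central point label
    whose centroid MDF is at or under the threshold.

    ``candidates`` is the output of :func:`reassign_small_clusters`.
    Returns final ``FiberCluster`` objects with recomputed centroids.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_central: dict = {}
    for i, (tup, _, _) in enumerate(candidates):
        c = _central_label(tup, point_subset)
        if c is not None:
            by_central.setdefault(c, []).append(i)

    cents = np.stack([c for _, _, c in candidates]) if n else np.empty((0, K_POINTS, 3))
    for idxs in by_central.values():
        if len(idxs) < 2:
            continue
        sub = np.array(idxs)
        dist = mdf_matrix(cents[sub], cents[sub])
        for a in range(len(sub)):
            for b in range(a + 1, len(sub)):
                if dist[a, b] <= merge_threshold_mm:
                    union(int(sub[a]), int(sub[b]))

    roots: dict = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)

    clusters = []
    for cid, members in enumerate(sorted(roots.values(), key=lambda m: m[0])):
        idx = np.concatenate([candidates[m][1] for m in members])
        idx = np.array(sorted(idx), dtype=int)
        clusters.append(FiberCluster(
            cluster_id=cid,
            member_indices=idx,
            centroid=mean_fiber(resampled[idx]),
            label_tuple=candidates[members[0]][0],
        ))
    return clusters


def compute_centroid(member_fibers: np.ndarray) -> np.ndarray:
    """Cluster centroid: pointwise mean of flip-aligned members (21 points).

    Members are co-oriented against the first member before averaging, so the
    result does not depend on storage direction.
    """
    return mean_fiber(member_fibers)


# ---------------------------------------------------------------------------
# Full stage
# ---------------------------------------------------------------------------

def cluster_tractogram(resampled: np.ndarray,
                       params: ClusteringParams | None = None) -> ClusterSet:
    """Run the four clustering steps on a stack of resampled fibers."""
    params = params or ClusteringParams()
    if resampled.shape[0] == 0:
        return ClusterSet(clusters=[], resampled=resampled, params=params)
    labels = cluster_points(resampled, params)
    groups = preliminary_clusters(labels)
    candidates = reassign_small_clusters(
        groups, resampled, params.reassign_threshold_mm, params.min_preliminary_size)
    clusters = merge_close_clusters(
        candidates, resampled, params.merge_threshold_mm, params.point_subset)
    return ClusterSet(clusters=clusters, resampled=resampled, params=params)
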