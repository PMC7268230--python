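"""Stage 2: cluster filtering by size and centroid length.

Short association (U-shaped) fibers sit in a narrow length band just under
the cortex; tiny clusters are mostly tractography noise.  A cluster survives
iff it has at least ``min_nf`` fibers and its centroid's polyline length lies
within ``[min_len, max_len]`` (boundaries inclusive).  The defaults —
10 fibers, 30 mm, 80 mm — are the standard operating point for whole-brain
short-bundle extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import fiber_length
from .intra import ClusterSet


@dataclass
class FilterParams:
    min_nf: int = 10
    min_len: float = 30.0
    max_len: float = 80.0

    def __post_init__(self):
        if self.min_nf < 1:
            raise ValueError("min_nf must be >= 1")
        if not (0 < self.min_len < self.max_len):
            raise ValueError("need 0 < min_len < max_len")


def keeps(cluster, params: FilterParams) -> bool:
    """Filtering predicate for a single cluster (inclusive boundaries)."""
    length = fiber_length(cluster.centroid)
    return (cluster.n_fibers >= params.min_nf
            and params.min_len <= length <= params.max_len)


def filter_clusters(cluster_set: ClusterSet,
                    params: FilterParams | None = None) -> ClusterSet:
    """Keep only clusters passing all three predicates; idempotent."""
    params = params or FilterParams()
    kept = [c for c in cluster_set.clusters if keeps(c, params)]
    return ClusterSet(clusters=kept, resampled=cluster_set.resampled,
                      params=cluster_set.params)
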