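"""End-to-end orchestration of the four intra-subject stages and the
group-wise relabeling, with config and per-stage logging.

``run_intra`` takes one subject's tractogram plus a labeled hemisphere mesh
and returns the named, position-indexed bundles; ``run_group`` takes the
intra-labeled cohort and applies one of the two inter-subject methods.
``run_cohort`` chains both over a synthetic (or loaded) cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import FilterParams, filter_clusters
from .geometry import resample_fibers
from .intersection import IntersectionRecord, build_grid, intersect_fiber
from .intra import ClusteringParams, ClusterSet, FiberCluster, cluster_tractogram
from .io import LabeledMesh, Tractogram
from .labeling import LabeledBundleSet, label_clusters
from .matching import CohortLabels, group_by_region_pair, match_cohort
from .qb import qb_cohort

log = logging.getLogger("swmlabel")


@dataclass
class PipelineConfig:
    """Resolved parameters of a full run; serializable for provenance."""

    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    filtering: FilterParams = field(default_factory=FilterParams)
    cell_size_mm: float = 1.5
    axis: str = "y"
    ascending: bool = True
    method: str = "qb"                 # 'match' or 'qb'
    threshold_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("match", "qb"):
            raise ValueError("method must be 'match' or 'qb'")
        self.clustering = dataclasses.replace(self.clustering,
                                              random_seed=self.seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=str, indent=2)


def apply_affine(tract: Tractogram, affine: np.ndarray) -> Tractogram:
    """Apply a user-supplied 4x4 affine to every fiber (mm -> mm)."""
    A = np.asarray(affine, dtype=float)
    if A.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    R, t = A[:3, :3], A[:3, 3]
    return Tractogram([f @ R.T + t for f in tract.fibers],
                      frame_id=tract.frame_id)


def run_intra(tract: Tractogram, mesh: LabeledMesh,
              config: PipelineConfig | None = None,
              subject_id: str = "subject") -> LabeledBundleSet:
    """Stages 1-4 on one subject and hemisphere."""
    config = config or PipelineConfig()
    log.info("[%s] config: %s", subject_id, config.to_json())

    resampled = resample_fibers(tract.fibers)
    cluster_set = cluster_tractogram(resampled, config.clustering)
    log.info("[%s] stage 1: %d fibers -> %d clusters",
             subject_id, len(tract), len(cluster_set))

    filtered = filter_clusters(cluster_set, config.filtering)
    log.info("[%s] stage 2: %d clusters survive filtering",
             subject_id, len(filtered))

    grid = build_grid(mesh, config.cell_size_mm)
    records = [IntersectionRecord()] * resampled.shape[0]
    needed = sorted({int(i) for c in filtered.clusters for i in c.member_indices})
    for i in needed:
        records[i] = intersect_fiber(resampled[i], mesh, grid)
    n_both = sum(records[i].both for i in needed)
    log.info("[%s] stage 3: %d/%d fibers intersect at both ends",
             subject_id, n_both, len(needed))

    bundles = label_clusters(filtered, records, mesh, subject_id=subject_id,
                             axis=config.axis, ascending=config.ascending,
                             grid=grid)
    log.info("[%s] stage 4: %d labeled bundles", subject_id, len(bundles))
    return bundles


def run_group(subject_sets: dict, config: PipelineConfig | None = None) -> CohortLabels:
    """Group-wise relabeling of intra-labeled subjects.

    Region-pair name components are preserved; only position indices are
    reassigned cohort-wide.
    """
    config = config or PipelineConfig()
    pair_map = group_by_region_pair(subject_sets)
    if config.method == "match":
        result = match_cohort(pair_map, config.threshold_mm)
    else:
        result = qb_cohort(pair_map, config.threshold_mm)
    log.info("group: method=%s threshold=%.1f mm -> %d labels over %d subjects",
             config.method, config.threshold_mm,
             result.table["new_label"].nunique(), len(subject_sets))
    return result


def run_cohort(tractograms: dict, mesh: LabeledMesh,
               config: PipelineConfig | None = None):
    """Intra-subject labeling of every tractogram, then group relabeling.

    All tractograms must share one spatial frame.
    Returns ``(subject_sets, cohort_labels)``.
    """
    config = config or PipelineConfig()
    frames = {t.frame_id for t in tractograms.values()}
    if len(frames) > 1:
        raise ValueError(f"tractograms are in mixed frames: {sorted(frames)}")
    subject_sets = {s: run_intra(tractograms[s], mesh, config, subject_id=s)
                    for s in sorted(tractograms)}
    return subject_sets, run_group(subject_sets, config)


# ---------------------------------------------------------------------------
# Flat-file serialization of intermediate stages (used by the CLI)
# ---------------------------------------------------------------------------

def save_cluster_assignment(cluster_set: ClusterSet, path) -> None:
    rows = [{"cluster_id": c.cluster_id, "fiber_index": int(i)}
            for c in cluster_set.clusters for i in c.member_indices]
    pd.DataFrame(rows, columns=["cluster_id", "fiber_index"]
                 ).to_csv(path, sep="\t", index=False)


def load_cluster_assignment(tract: Tractogram, path) -> ClusterSet:
    from .geometry import mean_fiber

    resampled = resample_fibers(tract.fibers)
    df = pd.read_csv(path, sep="\t")
    clusters = []
    for cid, grp in df.groupby("cluster_id"):
        idx = np.array(sorted(grp["fiber_index"]), dtype=int)
        clusters.append(FiberCluster(int(cid), idx, mean_fiber(resampled[idx])))
    return ClusterSet(clusters=clusters, resampled=resampled)


def save_records(records: list, path) -> None:
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "fiber_id": i, "tri_init": r.tri_init, "tri_end": r.tri_end,
            "x_init": r.point_init[0], "y_init": r.point_init[1],
            "z_init": r.point_init[2],
            "x_end": r.point_end[0], "y_end": r.point_end[1],
            "z_end": r.point_end[2],
            "u_init": r.uv_init[0], "v_init": r.uv_init[1],
            "u_end": r.uv_end[0], "v_end": r.uv_end[1],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_records(path) -> list:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, r in df.sort_values("fiber_id").iterrows():
        records.append(IntersectionRecord(
            tri_init=int(r["tri_init"]), tri_end=int(r["tri_end"]),
            point_init=np.array([r["x_init"], r["y_init"], r["z_init"]]),
            point_end=np.array([r["x_end"], r["y_end"], r["z_end"]]),
            uv_init=(r["u_init"], r["v_init"]),
            uv_end=(r["u_end"], r["v_end"]),
        ))
    return records


def save_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort as TCK + PLY + TSV files."""
    from .io import write_labeled_mesh, write_tractogram

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labeled_mesh(cohort.mesh, out / "mesh.ply", out / "mesh_labels.tsv",
                       out / "regions.tsv")
    for subject, tract in cohort.tractograms.items():
        write_tractogram(tract, out / f"{subject}.tck")
    cohort.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    cohort.families.to_csv(out / "families.tsv", sep="\t", index=False)
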