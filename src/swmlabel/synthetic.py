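"""Synthetic cohorts: parcellated meshes, planted U-bundles, ground truth.

Real inputs to the pipeline are whole-brain tractograms, cortical surface
meshes and per-vertex parcellation labels.  This module emulates all three
at desk scale so every stage can be exercised against a known answer:

* the "cortex" is an icosphere (default 50 mm radius) parcellated by
  nearest-seed-vertex assignment, with seed vertices chosen by farthest-point
  sampling so parcels are roughly even;
* a planted bundle is a U-shaped arc between two parcels: a spherical-linear
  path between the parcel-center directions whose radial profile starts just
  outside the surface, dives below it, and re-emerges at the far parcel —
  so both extremities cross the mesh inside the intended parcels.  Copies
  get Gaussian per-point jitter and a random storage direction (half the
  fibers reversed) to exercise the flip logic downstream;
* a cohort plants the same bundle families in several subjects, each family
  rigidly displaced per subject, plus unanchored noise fibers, and emits a
  ground-truth table (subject, fiber, family, parcel pair).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .geometry import mdf_matrix, resample_fiber
from .io import LabeledMesh, Tractogram, packaged_atlas_table


# ---------------------------------------------------------------------------
# Parcellated mesh
# ---------------------------------------------------------------------------

def _farthest_point_sample(vertices: np.ndarray, n: int, rng) -> np.ndarray:
    chosen = [int(rng.integers(len(vertices)))]
    d = np.linalg.norm(vertices - vertices[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(d.argmax())
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(vertices - vertices[nxt], axis=1))
    return np.array(chosen)


def make_parcellated_mesh(n_parcels: int = 12, subdivisions: int = 3,
                          seed: int = 0, radius: float = 50.0,
                          hemisphere: str = "lh") -> LabeledMesh:
    """Closed icosphere with every vertex assigned to one of ``n_parcels``
    regions (nearest seed vertex, Euclidean).

    Region indices and short names are drawn from the packaged
    Desikan–Killiany-style table, keeping the atlas's native numbering.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    rng = np.random.default_rng(seed)
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    vertices = np.asarray(sphere.vertices, dtype=float)
    triangles = np.asarray(sphere.faces, dtype=int)

    seeds = _farthest_point_sample(vertices, n_parcels, rng)
    atlas = packaged_atlas_table()
    indices = sorted(atlas)[:n_parcels]
    d = np.linalg.norm(vertices[:, None, :] - vertices[seeds][None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    vertex_labels = np.array([indices[i] for i in nearest])
    region_table = {i: atlas[i] for i in indices}
    return LabeledMesh(vertices, triangles, vertex_labels, region_table, hemisphere)


def parcel_centers(mesh: LabeledMesh) -> dict:
    """Unit direction of each parcel's vertex centroid (mesh centered at 0)."""
    out = {}
    for idx in mesh.region_table:
        pts = mesh.vertices[mesh.vertex_labels == idx]
        if len(pts) == 0:
            continue
        c = pts.mean(axis=0)
        out[idx] = c / np.linalg.norm(c)
    return out


# ---------------------------------------------------------------------------
# Planted bundles
# ---------------------------------------------------------------------------

def _slerp(ua: np.ndarray, ub: np.ndarray, s: np.ndarray) -> np.ndarray:
    omega = np.arccos(np.clip(ua @ ub, -1.0, 1.0))
    if omega < 1e-9:
        return np.repeat(ua[None], len(s), axis=0)
    return (np.sin((1 - s)[:, None] * omega) * ua[None]
            + np.sin(s[:, None] * omega) * ub[None]) / np.sin(omega)


def _u_arc(ua, ub, radius, end_offset=-1.0, depth=12.0, n_points=25):
    """U-shaped arc from direction ``ua`` to ``ub``.

    The radial profile ``r(s) = (R + e) - (e + depth) * sin(pi s)^0.4``
    starts ``end_offset`` mm relative to the surface (negative = just
    underneath, where tractography streamlines terminate at the white–gray
    boundary; the forward projection of the intersection search is what
    catches such extremities), dives steeply — the sub-linear exponent keeps
    the descent fast near the extremities — and bottoms out ``depth`` mm
    under the surface.
    """
    s = np.linspace(0.0, 1.0, n_points)
    dirs = _slerp(ua, ub, s)
    r = (radius + end_offset) - (end_offset + depth) * np.sin(np.pi * s) ** 0.4
    return dirs * r[:, None]


def make_bundle(mesh: LabeledMesh, parcel_a: int, parcel_b: int,
                n_fibers: int, jitter: float, seed: int,
                anchors: tuple | None = None, depth: float = 8.0) -> tuple:
    """Plant one bundle of ``n_fibers`` jittered copies of a U-arc between
    two parcels.

    Returns ``(fibers, canonical_arc)``; fibers are (25, 3) polylines with
    Gaussian point jitter and randomized storage direction.
    """
    if parcel_a == parcel_b:
        raise ValueError("parcels must be distinct")
    rng = np.random.default_rng(seed)
    radius = float(np.linalg.norm(mesh.vertices, axis=1).mean())
    if anchors is None:
        centers = parcel_centers(mesh)
        ua, ub = centers[parcel_a], centers[parcel_b]
    else:
        ua, ub = anchors
    arc = _u_arc(ua, ub, radius, depth=depth)
    fibers = []
    for _ in range(n_fibers):
        f = arc + rng.normal(0.0, jitter, arc.shape)
        if rng.random() < 0.5:
            f = f[::-1]
        fibers.append(f)
    return fibers, arc


def _noise_fiber(rng, radius):
    """A random gentle polyline not anchored to any parcel (quadratic Bezier
    inside/around the mesh)."""
    ctrl = rng.uniform(-1.0, 1.0, (3, 3))
    ctrl /= np.maximum(np.linalg.norm(ctrl, axis=1, keepdims=True), 1e-9)
    ctrl *= rng.uniform(0.3, 1.05, (3, 1)) * radius
    t = np.linspace(0, 1, 15)[:, None]
    return ((1 - t) ** 2 * ctrl[0] + 2 * (1 - t) * t * ctrl[1] + t ** 2 * ctrl[2])


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a synthetic multi-subject cohort."""

    n_subjects: int = 5
    n_families: int = 15
    fibers_per_bundle: tuple = (30, 60)
    jitter_mm: float = 1.0
    subject_sigma_mm: float = 2.0
    n_noise_fibers: int = 200
    presence: np.ndarray | None = None     # (families, subjects) bool
    random_seed: int = 0
    n_parcels: int = 16
    subdivisions: int = 3
    radius_mm: float = 50.0
    min_family_separation_mm: float = 12.0
    angle_window: tuple = (0.6, 1.1)       # rad, sets arc lengths ~40-65 mm

    def __post_init__(self):
        if self.jitter_mm < 0 or self.subject_sigma_mm < 0:
            raise ValueError("sigmas must be non-negative")
        if self.presence is not None:
            self.presence = np.asarray(self.presence, dtype=bool)
            if self.presence.shape != (self.n_families, self.n_subjects):
                raise ValueError("presence matrix shape mismatch")


@dataclass
class Cohort:
    """Generated cohort: shared mesh, per-subject tractograms, ground truth."""

    mesh: LabeledMesh
    tractograms: dict                      # subject id -> Tractogram
    truth: pd.DataFrame                    # subject, fiber_index, family, parcel_a, parcel_b
    families: pd.DataFrame                 # family, parcel_a, parcel_b
    spec: CohortSpec = field(default=None)

    @property
    def subjects(self):
        return sorted(self.tractograms)


def _select_family_pairs(mesh, spec, rng):
    """Parcel pairs whose U-arcs are well separated and filter-window sized."""
    centers = parcel_centers(mesh)
    idxs = sorted(centers)
    candidates = []
    for i, a in enumerate(idxs):
        for b in idxs[i + 1:]:
            ang = float(np.arccos(np.clip(centers[a] @ centers[b], -1, 1)))
            if spec.angle_window[0] <= ang <= spec.angle_window[1]:
                candidates.append((a, b))
    rng.shuffle(candidates)
    chosen, arcs = [], []
    for a, b in candidates:
        arc = resample_fiber(_u_arc(centers[a], centers[b], spec.radius_mm))
        if arcs and mdf_matrix(arc[None], np.stack(arcs)).min() < spec.min_family_separation_mm:
            continue
        chosen.append((a, b))
        arcs.append(arc)
        if len(chosen) == spec.n_families:
            return chosen
    raise ValueError(
        f"only {len(chosen)} well-separated parcel pairs available; "
        f"reduce n_families or n_parcels constraints")


def make_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate the full synthetic cohort described by ``spec``."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.random_seed)
    mesh = make_parcellated_mesh(spec.n_parcels, spec.subdivisions,
                                 seed=spec.random_seed, radius=spec.radius_mm)
    pairs = _select_family_pairs(mesh, spec, rng)
    presence = (spec.presence if spec.presence is not None
                else np.ones((spec.n_families, spec.n_subjects), dtype=bool))

    centers = parcel_centers(mesh)
    subjects = [f"sub{k:03d}" for k in range(spec.n_subjects)]
    tractograms, truth_rows = {}, []
    lo, hi = spec.fibers_per_bundle
    for sj, subject in enumerate(subjects):
        fibers = []
        for fam, (a, b) in enumerate(pairs):
            if not presence[fam, sj]:
                continue
            nf = int(rng.integers(lo, hi + 1))
            bundle, _ = make_bundle(mesh, a, b, nf, spec.jitter_mm,
                                    seed=int(rng.integers(2 ** 31)))
            # Inter-subject variability slides a family along the cortex
            # (tangential to the family's mid-direction) rather than
            # detaching it radially: bundles stay attached to the shared
            # synthetic surface, as they would to each subject's own cortex.
            shift = rng.normal(0.0, spec.subject_sigma_mm, 3)
            um = centers[a] + centers[b]
            um /= np.linalg.norm(um)
            shift = shift - (shift @ um) * um
            for f in bundle:
                truth_rows.append({"subject": subject, "fiber_index": len(fibers),
                                   "family": fam, "parcel_a": a, "parcel_b": b})
                fibers.append(f + shift)
        for _ in range(spec.n_noise_fibers):
            truth_rows.append({"subject": subject, "fiber_index": len(fibers),
                               "family": -1, "parcel_a": -1, "parcel_b": -1})
            fibers.append(_noise_fiber(rng, spec.radius_mm))
        tractograms[subject] = Tractogram(fibers=fibers, frame_id="synthetic-mni")

    truth = pd.DataFrame(truth_rows,
                         columns=["subject", "fiber_index", "family",
                                  "parcel_a", "parcel_b"])
    families = pd.DataFrame(
        [{"family": i, "parcel_a": a, "parcel_b": b}
         for i, (a, b) in enumerate(pairs)])
    return Cohort(mesh=mesh, tractograms=tractograms, truth=truth,
                  families=families, spec=spec)
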