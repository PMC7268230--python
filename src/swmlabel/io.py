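"""Reading and writing tractograms, labeled meshes and labeled-bundle outputs.

Streamline formats (TRK, TCK) are handled by :mod:`nibabel.streamlines`;
surface meshes (PLY, OFF) by :mod:`trimesh`.  A plain-text interchange format
for tractograms is provided for small fixtures: one ``x y z`` line per point,
fibers separated by blank lines, with an optional ``# frame=...`` header.
No canonical fiber orientation is assumed anywhere: fibers are stored and
returned exactly in the order found on disk.

Coordinates are millimetres in a right-handed (RAS-like) frame throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import fiber_length


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under the named dialect."""


# ---------------------------------------------------------------------------
# Tractograms
# ---------------------------------------------------------------------------

@dataclass
class Tractogram:
    """A whole-brain set of streamlines.

    Attributes
    ----------
    fibers : list of (n_i, 3) float arrays
        Each fiber has >= 2 points; coordinates in mm.
    frame_id : str
        Free-text tag naming the spatial frame the coordinates live in.
    """

    fibers: list = field(default_factory=list)
    frame_id: str = ""

    def __post_init__(self):
        self.fibers = [np.asarray(f, dtype=float) for f in self.fibers]
        for i, f in enumerate(self.fibers):
            if f.ndim != 2 or f.shape[0] < 2 or f.shape[1] != 3:
                raise FormatError(f"fiber {i}: expected (n>=2, 3) points, got {f.shape}")
            if not np.all(np.isfinite(f)):
                raise FormatError(f"fiber {i}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.fibers)


def _infer_format(path, fmt=None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("trk", "tck", "txt"):
        return suffix
    raise FormatError(f"cannot infer tractogram format from {path!r}")


def read_tractogram(path, fmt: str | None = None) -> Tractogram:
    """Read a tractogram from TRK, TCK or the plain-text interchange format.

    Point order is preserved exactly as stored; no orientation is imposed.
    """
    fmt = _infer_format(path, fmt)
    if fmt in ("trk", "tck"):
        try:
            obj = nib.streamlines.load(str(path))
        except Exception as exc:  # nibabel raises assorted types
            raise FormatError(f"cannot read {fmt.upper()} file {path}: {exc}") from exc
        fibers = [np.asarray(s, dtype=float) for s in obj.streamlines]
        return Tractogram(fibers=fibers, frame_id="rasmm")
    if fmt == "txt":
        return _read_text_tractogram(path)
    raise FormatError(f"unknown tractogram format {fmt!r}")


def _read_text_tractogram(path) -> Tractogram:
    frame_id = ""
    fibers, current = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                if "frame=" in line:
                    frame_id = line.split("frame=", 1)[1].strip()
                continue
            if not line:
                if current:
                    fibers.append(np.array(current, dtype=float))
                    current = []
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                current.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if current:
        fibers.append(np.array(current, dtype=float))
    return Tractogram(fibers=fibers, frame_id=frame_id)


def write_tractogram(tract: Tractogram, path, fmt: str | None = None) -> None:
    """Write a tractogram as TRK, TCK or plain text."""
    fmt = _infer_format(path, fmt)
    if fmt in ("trk", "tck"):
        nib_t = nib.streamlines.Tractogram(
            [np.asarray(f, dtype=np.float32) for f in tract.fibers],
            affine_to_rasmm=np.eye(4),
        )
        cls = nib.streamlines.TrkFile if fmt == "trk" else nib.streamlines.TckFile
        cls(nib_t).save(str(path))
        return
    if fmt == "txt":
        with open(path, "w") as fh:
            fh.write(f"# swmlabel tractogram frame={tract.frame_id}\n")
            for f in tract.fibers:
                for p in f:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
                fh.write("\n")
        return
    raise FormatError(f"unknown tractogram format {fmt!r}")


# ---------------------------------------------------------------------------
# Labeled meshes
# ---------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Triangle mesh with one atlas region label per vertex.

    ``region_table`` maps the atlas's native integer indices to short names
    (e.g. ``22 -> "PoC"``, ``24 -> "PrC"``); the native numbering is kept
    because the bundle-naming rule orders region pairs by it.  Triangle
    indices are 0-based internally.
    """

    vertices: np.ndarray          # (N, 3) mm
    triangles: np.ndarray         # (M, 3) int, 0-based
    vertex_labels: np.ndarray     # (N,) int
    region_table: dict            # region index -> short name
    hemisphere: str = "lh"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=int)
        n = self.vertices.shape[0]
        if self.vertex_labels.shape[0] != n:
            raise ValueError(
                f"label count {self.vertex_labels.shape[0]} != vertex count {n}"
            )
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise ValueError("triangle indices out of range [0, N)")
        present = set(np.unique(self.vertex_labels).tolist())
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"region_table missing indices {sorted(missing)}")
        if self.hemisphere not in ("lh", "rh"):
            raise ValueError("hemisphere must be 'lh' or 'rh'")


def read_labeled_mesh(mesh_path, labels_path, region_table_path,
                      hemisphere: str = "lh") -> LabeledMesh:
    """Load a PLY/OFF mesh plus per-vertex label and region tables.

    ``labels_path``: two-column TSV (vertex_index, region_index) with header;
    ``region_table_path``: TSV (region_index, short_name) with header.
    """
    mesh = trimesh.load_mesh(str(mesh_path), process=False)
    vertices = np.asarray(mesh.vertices, dtype=float)
    triangles = np.asarray(mesh.faces, dtype=int)

    lab = pd.read_csv(labels_path, sep="\t")
    if lab.shape[0] != vertices.shape[0]:
        raise ValueError(
            f"label table has {lab.shape[0]} rows but mesh has "
            f"{vertices.shape[0]} vertices"
        )
    order = np.argsort(lab["vertex_index"].to_numpy())
    vertex_labels = lab["region_index"].to_numpy()[order]

    reg = pd.read_csv(region_table_path, sep="\t")
    region_table = dict(zip(reg["region_index"].astype(int), reg["short_name"].astype(str)))
    return LabeledMesh(vertices, triangles, vertex_labels, region_table, hemisphere)


def write_labeled_mesh(mesh: LabeledMesh, mesh_path, labels_path,
                       region_table_path) -> None:
    """Write mesh (PLY/OFF by extension) and the two TSV tables."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    tm.export(str(mesh_path))
    pd.DataFrame({
        "vertex_index": np.arange(mesh.vertices.shape[0]),
        "region_index": mesh.vertex_labels,
    }).to_csv(labels_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(mesh.region_table.items()),
        columns=["region_index", "short_name"],
    ).to_csv(region_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Labeled bundle sets
# ---------------------------------------------------------------------------

def write_labeled_bundles(bundle_set, out_dir, fmt: str = "tck") -> Path:
    """Write one streamline file per labeled bundle plus a TSV manifest.

    Files are named ``<hemi>_<RegionA>-<RegionB>_<index>.<fmt>``; the manifest
    (``bundles.tsv``) lists subject, label, n_fibers and centroid length.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seen = set()
    for b in bundle_set.bundles:
        name = b.label.render()
        if name in seen:
            raise ValueError(f"duplicate bundle label {name!r}")
        seen.add(name)
        write_tractogram(Tractogram(list(b.fibers), frame_id="rasmm"),
                         out_dir / f"{name}.{fmt}")
        rows.append({
            "subject": bundle_set.subject_id,
            "label": name,
            "n_fibers": len(b.fibers),
            "centroid_length_mm": round(fiber_length(b.centroid), 4),
        })
    manifest = out_dir / "bundles.tsv"
    pd.DataFrame(rows, columns=["subject", "label", "n_fibers", "centroid_length_mm"]
                 ).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_region_table(path) -> dict:
    """Read a TSV (region_index, short_name) into a dict."""
    reg = pd.read_csv(path, sep="\t")
    return dict(zip(reg["region_index"].astype(int), reg["short_name"].astype(str)))


def packaged_atlas_table() -> dict:
    """The packaged Desikan–Killiany-style region table (index -> short name)."""
    path = os.path.join(os.path.dirname(__file__), "data", "dk_regions.tsv")
    return read_region_table(path)
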