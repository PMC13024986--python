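"""Triangle-mesh data model, standard-format I/O and surface planimetry.

Vertices are always in millimeters (structured-light scanners export
millimeter geometry); reported areas are in cm², the unit clinicians use
for wound size. The mm²→cm² conversion happens in exactly one place,
:func:`surface_area`, so every other operation works in native mm².

Meshes are open surfaces: wound scans cover only the affected region and
are never watertight, and no operation here assumes or enforces closure.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import (
    EmptyMeshError,
    EmptySelectionError,
    MeshReadError,
    UnsupportedFormatError,
)

#: Faces with area at or below this (mm²) are treated as numerically
#: collapsed. Far below scanner resolution (~0.2 mm point spacing), so
#: only genuinely degenerate triangles are removed.
DEFAULT_AREA_EPSILON = 1e-8

_SUPPORTED_FORMATS = {"ply", "obj", "stl"}


@dataclass
class TriangleMesh:
    """A triangulated surface with optional per-vertex color and label channels.

    Parameters
    ----------
    vertices : (n, 3) float array, millimeters.
    faces : (m, 3) int array of vertex indices.
    vertex_colors : optional (n, 3) float array, RGB in [0, 1].
    vertex_labels : optional (n,) int array; 0 = background skin,
        positive values identify wound regions.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None
    vertex_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face indices out of range")
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.float64).reshape(-1, 3)
            if len(self.vertex_colors) != n:
                raise ValueError("vertex_colors must have one entry per vertex")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64).reshape(-1)
            if len(self.vertex_labels) != n:
                raise ValueError("vertex_labels must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face areas in mm²: half the cross-product magnitude of two edges."""
    v = mesh.vertices
    f = mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def surface_area(mesh: TriangleMesh, face_subset=None) -> float:
    """Total surface area in cm², over ``face_subset`` or the whole mesh.

    Additive over disjoint subsets by construction (a plain sum).
    An empty subset yields 0.0 with a warning rather than an error, since
    a fully healed wound legitimately has no selectable faces.
    """
    areas = face_areas(mesh)
    if face_subset is not None:
        idx = np.asarray(sorted(face_subset), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_faces):
            raise IndexError("face subset index out of range")
        if idx.size == 0:
            warnings.warn("empty face subset: surface area is 0", stacklevel=2)
            return 0.0
        areas = areas[idx]
    return float(areas.sum()) / 100.0


def validate_mesh(mesh: TriangleMesh, area_epsilon: float = DEFAULT_AREA_EPSILON) -> TriangleMesh:
    """Return a cleaned copy: no degenerate faces, no unreferenced vertices.

    Removes faces that repeat a vertex or whose area is <= ``area_epsilon``
    mm² (scanner-noise slivers), then drops vertices no surviving face
    references, re-indexing the color/label channels consistently.

    Raises
    ------
    EmptyMeshError
        If no valid face remains.
    """
    keep = (
        (mesh.faces[:, 0] != mesh.faces[:, 1])
        & (mesh.faces[:, 1] != mesh.faces[:, 2])
        & (mesh.faces[:, 0] != mesh.faces[:, 2])
        & (face_areas(mesh) > area_epsilon)
    )
    faces = mesh.faces[keep]
    if len(faces) == 0:
        raise EmptyMeshError("no valid faces remain after cleaning")
    used, inverse = np.unique(faces, return_inverse=True)
    return TriangleMesh(
        vertices=mesh.vertices[used],
        faces=inverse.reshape(-1, 3),
        vertex_colors=None if mesh.vertex_colors is None else mesh.vertex_colors[used],
        vertex_labels=None if mesh.vertex_labels is None else mesh.vertex_labels[used],
    )


def submesh(mesh: TriangleMesh, face_set) -> TriangleMesh:
    """Extract the mesh restricted to ``face_set``, vertices re-indexed.

    Raises
    ------
    EmptySelectionError
        If ``face_set`` is empty.
    """
    idx = np.asarray(sorted(face_set), dtype=np.int64)
    if idx.size == 0:
        raise EmptySelectionError("cannot build a submesh from an empty face set")
    faces = mesh.faces[idx]
    used, inverse = np.unique(faces, return_inverse=True)
    return TriangleMesh(
        vertices=mesh.vertices[used],
        faces=inverse.reshape(-1, 3),
        vertex_colors=None if mesh.vertex_colors is None else mesh.vertex_colors[used],
        vertex_labels=None if mesh.vertex_labels is None else mesh.vertex_labels[used],
    )


def _infer_format(path: Path, format_hint: str | None) -> str:
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise UnsupportedFormatError(f"unsupported mesh format {fmt!r} (supported: ply, obj, stl)")
    return fmt


def read_mesh(path, format_hint: str | None = None, labels_path=None) -> TriangleMesh:
    """Read a PLY/OBJ/STL file (ASCII or binary dialects) into a TriangleMesh.

    Per-vertex colors are picked up when the file carries them (PLY
    red/green/blue properties, OBJ vertex-line color extensions); STL
    carries geometry only. Integer wound labels live in a sidecar CSV
    (``vertex_index,label``) because none of the three formats
    standardizes them; pass it as ``labels_path``.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if not path.is_file():
        raise MeshReadError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises many concrete types
        raise MeshReadError(f"could not parse {path} as {fmt}: {exc}") from exc
    if tm.faces is None or len(tm.faces) == 0:
        raise MeshReadError(f"{path} contains no triangles")

    colors = None
    visual = getattr(tm, "visual", None)
    if visual is not None and getattr(visual, "kind", None) == "vertex":
        rgba = np.asarray(visual.vertex_colors, dtype=np.float64)
        if len(rgba) == len(tm.vertices):
            colors = rgba[:, :3] / 255.0

    labels = None
    if labels_path is not None:
        labels = read_labels(labels_path, len(tm.vertices))

    return TriangleMesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
        vertex_colors=colors,
        vertex_labels=labels,
    )


def write_mesh(path, mesh: TriangleMesh, format_hint: str | None = None,
               labels_path=None) -> None:
    """Write a mesh as ASCII PLY/OBJ/STL (format taken from the extension).

    ASCII dialects are written so outputs diff cleanly under version
    control. Colors are embedded for PLY/OBJ; labels, when present and a
    ``labels_path`` is given, go to the sidecar CSV.
    """
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if mesh.vertex_colors is not None and fmt in ("ply", "obj"):
        rgba = np.empty((mesh.n_vertices, 4), dtype=np.uint8)
        rgba[:, :3] = np.clip(np.round(mesh.vertex_colors * 255.0), 0, 255).astype(np.uint8)
        rgba[:, 3] = 255
        tm.visual.vertex_colors = rgba
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data)
    elif fmt == "obj":
        text = trimesh.exchange.obj.export_obj(tm, include_color=True, digits=10)
        path.write_text(text)
    else:  # stl, ASCII dialect
        path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
    if labels_path is not None and mesh.vertex_labels is not None:
        write_labels(labels_path, mesh.vertex_labels)


def read_labels(path, n_vertices: int) -> np.ndarray:
    """Read a vertex-label sidecar CSV into a dense (n_vertices,) int array.

    Vertices absent from the file default to label 0 (background skin).
    """
    labels = np.zeros(n_vertices, dtype=np.int64)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and header[:2] != ["vertex_index", "label"]:
            # no header line: first row is data
            labels[int(header[0])] = int(header[1])
        for row in reader:
            if not row:
                continue
            i = int(row[0])
            if i < 0 or i >= n_vertices:
                raise MeshReadError(f"label sidecar references vertex {i} outside mesh")
            labels[i] = int(row[1])
    return labels


def write_labels(path, labels: np.ndarray) -> None:
    """Write nonzero vertex labels to a sidecar CSV (vertex_index,label)."""
    labels = np.asarray(labels)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_index", "label"])
        for i in np.nonzero(labels)[0]:
            writer.writerow([int(i), int(labels[i])])
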