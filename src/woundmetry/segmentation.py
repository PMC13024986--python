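"""Wound region-of-interest extraction on triangulated scans.

A clinician (or the synthetic generator) delineates the wound either as
per-vertex integer labels, as a color rule on the scan's texture, or as
a boundary loop of vertices; these operations turn any of the three into
a face-level ROI whose summed triangle areas give the wound area.

A face counts as wound under the conservative ``all_vertices`` rule only
when every one of its three corners is wound-positive, so boundary
triangles are never charged to the wound; the ``majority`` rule (>= 2 of
3 corners) is available where an unbiased boundary split is preferred.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _csgraph_components

from .exceptions import ConfigurationError, EmptySelectionError
from .mesh import TriangleMesh, face_areas, surface_area

INCLUSION_RULES = ("all_vertices", "majority")


@dataclass(frozen=True)
class RoiSelection:
    """A set of mesh faces identified as wound, with selection provenance.

    ``area_cm2`` is recomputed from the mesh at construction time, never
    cached from an earlier state of the selection.
    """

    face_indices: np.ndarray
    source: str  # labels | color_rule | boundary_loop
    area_cm2: float
    label_value: int | None = None

    def __len__(self) -> int:
        return len(self.face_indices)


def _make_selection(mesh: TriangleMesh, faces: np.ndarray, source: str,
                    label_value: int | None = None) -> RoiSelection:
    faces = np.asarray(sorted(faces), dtype=np.int64)
    if faces.size == 0:
        raise EmptySelectionError(f"{source} selection matched no faces")
    return RoiSelection(
        face_indices=faces,
        source=source,
        area_cm2=surface_area(mesh, faces),
        label_value=label_value,
    )


def _faces_from_vertex_mask(mesh: TriangleMesh, positive: np.ndarray,
                            inclusion_rule: str) -> np.ndarray:
    if inclusion_rule not in INCLUSION_RULES:
        raise ValueError(f"inclusion_rule must be one of {INCLUSION_RULES}")
    hits = positive[mesh.faces].sum(axis=1)
    need = 3 if inclusion_rule == "all_vertices" else 2
    return np.nonzero(hits >= need)[0]


def roi_from_labels(mesh: TriangleMesh, label_value: int = 1,
                    inclusion_rule: str = "all_vertices") -> RoiSelection:
    """Select wound faces from the vertex-label channel.

    Raises
    ------
    ConfigurationError
        If the mesh carries no label channel.
    EmptySelectionError
        If no face satisfies the inclusion rule.
    """
    if mesh.vertex_labels is None:
        raise ConfigurationError("mesh has no vertex label channel")
    positive = mesh.vertex_labels == label_value
    faces = _faces_from_vertex_mask(mesh, positive, inclusion_rule)
    return _make_selection(mesh, faces, "labels", label_value)


def roi_from_color(mesh: TriangleMesh, channel_weights=(1.0, -1.0, -1.0),
                   threshold: float = 0.0, polarity: str = "above",
                   inclusion_rule: str = "all_vertices"):
    """Select wound faces by thresholding a weighted color score per vertex.

    The score is the dot product of ``channel_weights`` with the vertex
    RGB; a vertex is wound-positive when the score is >= ``threshold``
    (``polarity='above'``) or <= it (``'below'``). The default weights
    (1, -1, -1) separate red wound tissue from skin tones.

    Returns
    -------
    (RoiSelection, ndarray)
        The selection and the induced per-vertex labeling (1 = wound),
        suitable for re-running through :func:`roi_from_labels`.
    """
    if mesh.vertex_colors is None:
        raise ConfigurationError("mesh has no vertex color channel")
    if polarity not in ("above", "below"):
        raise ValueError("polarity must be 'above' or 'below'")
    score = mesh.vertex_colors @ np.asarray(channel_weights, dtype=np.float64)
    positive = score >= threshold if polarity == "above" else score <= threshold
    if positive.all() or not positive.any():
        warnings.warn(
            "degenerate color threshold: selected "
            + ("all" if positive.all() else "no") + " vertices",
            stacklevel=2,
        )
    induced = positive.astype(np.int64)
    faces = _faces_from_vertex_mask(mesh, positive, inclusion_rule)
    selection = _make_selection(mesh, faces, "color_rule")
    return selection, induced


def roi_from_boundary_loop(mesh: TriangleMesh, loop_vertices, seed_vertex: int,
                           inclusion_rule: str = "all_vertices") -> RoiSelection:
    """Select the wound as the vertex region flood-filled from ``seed_vertex``
    without crossing ``loop_vertices``.

    The loop is converted to an induced vertex labeling (region + loop
    itself = wound) and selection proceeds through the label pathway, so
    the result is identical to supplying those labels directly.
    """
    loop = np.zeros(mesh.n_vertices, dtype=bool)
    loop[np.asarray(list(loop_vertices), dtype=np.int64)] = True
    if loop[seed_vertex]:
        raise ValueError("seed vertex lies on the boundary loop")
    # vertex adjacency restricted to non-loop vertices
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    ok = ~(loop[edges[:, 0]] | loop[edges[:, 1]])
    edges = edges[ok]
    n = mesh.n_vertices
    graph = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, comp = _csgraph_components(graph, directed=False)
    region = comp == comp[seed_vertex]
    positive = region | loop
    induced = np.zeros(n, dtype=np.int64)
    induced[positive] = 1
    labeled = TriangleMesh(mesh.vertices, mesh.faces, mesh.vertex_colors, induced)
    sel = roi_from_labels(labeled, 1, inclusion_rule)
    return RoiSelection(sel.face_indices, "boundary_loop", sel.area_cm2, None)


def connected_components(mesh: TriangleMesh, face_set) -> list[np.ndarray]:
    """Partition a face set into edge-connected components.

    Faces are adjacent iff they share an edge (shared-vertex contact does
    not merge patches touching at a point). Components are ordered by
    descending area, ties broken by smallest contained face index.
    """
    idx = np.asarray(sorted(face_set), dtype=np.int64)
    if idx.size == 0:
        return []
    f = mesh.faces[idx]
    # map each sorted edge to the (local) faces using it
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    owner = np.tile(np.arange(len(idx)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = (np.diff(edges[:, 0]) == 0) & (np.diff(edges[:, 1]) == 0)
    a = owner[:-1][same]
    b = owner[1:][same]
    graph = coo_matrix(
        (np.ones(len(a)), (a, b)), shape=(len(idx), len(idx))
    )
    n_comp, comp = _csgraph_components(graph, directed=False)
    areas = face_areas(mesh)
    parts = []
    for c in range(n_comp):
        members = idx[comp == c]
        parts.append((float(areas[members].sum()), -int(members.min()), members))
    parts.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return [members for _, _, members in parts]


def filter_components(components, mesh: TriangleMesh, min_area_cm2: float,
                      source: str = "labels") -> RoiSelection:
    """Union the components whose area is >= ``min_area_cm2``.

    Suppresses speckle selections (stray mislabeled patches) the way
    artifact removal suppresses scanner noise.

    Raises
    ------
    EmptySelectionError
        If every component falls below the threshold.
    """
    kept = [c for c in components if surface_area(mesh, c) >= min_area_cm2]
    if not kept:
        raise EmptySelectionError(
            f"no connected component reaches {min_area_cm2} cm2"
        )
    return _make_selection(mesh, np.concatenate(kept), source)
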