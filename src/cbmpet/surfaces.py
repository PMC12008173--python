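"""Triangulated cortical surfaces and per-vertex scalar fields.

Surfaces and fields round-trip through the FreeSurfer binary dialects
(``read_geometry``/``read_morph_data`` via nibabel) so outputs open in
standard surface viewers; a plain CSV escape hatch is provided for both.
Vertex indices are 0-based, coordinates in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel.freesurfer.io as fsio
import numpy as np
from scipy import sparse

from .errors import FormatError, GeometryError, ShapeError

__all__ = [
    "SurfaceMesh",
    "VertexField",
    "read_surface",
    "write_surface",
    "read_vertex_field",
    "write_vertex_field",
    "surface_to_csv",
    "surface_from_csv",
    "field_to_csv",
    "field_from_csv",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh: ``vertices`` (N,3) mm, ``faces`` (M,3) 0-based indices.

    Edge adjacency, edge lengths and per-vertex areas (one third of each
    incident triangle) are derived lazily and cached.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise GeometryError("face indexes a vertex outside the mesh")
        areas = self.face_areas()
        if np.any(areas <= 0):
            raise GeometryError("mesh contains degenerate (zero-area) faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E,2) array, i<j."""
        if "edges" not in self._cache:
            e = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def edge_lengths(self) -> np.ndarray:
        if "edge_lengths" not in self._cache:
            e = self.edges()
            self._cache["edge_lengths"] = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
        return self._cache["edge_lengths"]

    def adjacency(self, weighted: bool = True) -> sparse.csr_matrix:
        """Symmetric sparse adjacency; weights are edge lengths in mm."""
        key = ("adj", weighted)
        if key not in self._cache:
            e = self.edges()
            w = self.edge_lengths() if weighted else np.ones(len(e))
            n = self.n_vertices
            m = sparse.coo_matrix(
                (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(n, n),
            )
            self._cache[key] = m.tocsr()
        return self._cache[key]

    def vertex_areas(self) -> np.ndarray:
        """One third of the summed incident-triangle areas, per vertex."""
        if "vertex_areas" not in self._cache:
            fa = self.face_areas() / 3.0
            va = np.zeros(self.n_vertices)
            for i in range(3):
                np.add.at(va, self.faces[:, i], fa)
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]


@dataclass
class VertexField:
    """Per-vertex scalars tied to a mesh by length; ``units`` is a label."""

    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("vertex field contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def check_mesh(self, mesh: SurfaceMesh) -> None:
        if len(self.values) != mesh.n_vertices:
            raise ShapeError(
                f"field length {len(self.values)} != mesh vertex count {mesh.n_vertices}"
            )


def read_surface(path) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface."""
    try:
        vertices, faces = fsio.read_geometry(str(path))
    except Exception as exc:
        raise FormatError(f"not a valid FreeSurfer surface file {path}: {exc}") from exc
    return SurfaceMesh(vertices, faces)


def write_surface(mesh: SurfaceMesh, path) -> None:
    fsio.write_geometry(str(path), mesh.vertices.astype(np.float32), mesh.faces)


def read_vertex_field(path, mesh: SurfaceMesh | None = None, units: str = "arbitrary") -> VertexField:
    """Read a FreeSurfer curv ("morph data") file, optionally length-checked."""
    try:
        values = fsio.read_morph_data(str(path))
    except Exception as exc:
        raise FormatError(f"not a valid FreeSurfer curv file {path}: {exc}") from exc
    field = VertexField(values, units=units)
    if mesh is not None:
        field.check_mesh(mesh)
    return field


def write_vertex_field(field: VertexField, path, mesh: SurfaceMesh | None = None) -> None:
    if mesh is not None:
        field.check_mesh(mesh)
    fsio.write_morph_data(str(path), field.values.astype(np.float32))


# --- plain-text escape hatches -------------------------------------------

def surface_to_csv(mesh: SurfaceMesh, vertices_path, faces_path) -> None:
    np.savetxt(vertices_path, mesh.vertices, delimiter=",", header="x,y,z", comments="")
    np.savetxt(faces_path, mesh.faces, fmt="%d", delimiter=",", header="v0,v1,v2", comments="")


def surface_from_csv(vertices_path, faces_path) -> SurfaceMesh:
    v = np.loadtxt(vertices_path, delimiter=",", skiprows=1)
    f = np.loadtxt(faces_path, delimiter=",", skiprows=1, dtype=np.int64)
    return SurfaceMesh(v, f)


def field_to_csv(field: VertexField, path) -> None:
    np.savetxt(path, field.values, delimiter=",", header="value", comments="")


def field_from_csv(path, units: str = "arbitrary") -> VertexField:
    return VertexField(np.loadtxt(path, delimiter=",", skiprows=1), units=units)
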