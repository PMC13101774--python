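"""Triangle-mesh data model and geometry utilities.

The surface mesh is the spatial domain of every analysis in this package: the
Laplace-Beltrami operator is assembled on it, per-vertex scalar maps (cortical
thickness, t-statistics, eigenmode patterns) live on its vertices, and cluster
areas are measured on it.  Vertex indices are 0-based everywhere, including
label files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "SurfaceMap",
    "MeshCluster",
    "DegenerateFaceError",
    "make_icosphere",
    "vertex_areas",
    "mesh_clusters",
]


class DegenerateFaceError(ValueError):
    """A face has (numerically) zero area."""


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    e1 = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    e2 = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


@dataclass
class TriangleMesh:
    """A triangulated surface with ``vertices`` (n, 3) in mm and ``faces`` (m, 3).

    Parameters
    ----------
    vertices
        Cartesian vertex coordinates, one row per vertex, in mm.
    faces
        0-based vertex-index triples, one row per triangle.
    name
        Optional identifier (e.g. ``"lh.pial"``).
    hemisphere
        Optional ``"lh"``/``"rh"`` tag.
    allow_disconnected
        Permit meshes with more than one edge-connected component.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str | None = None
    hemisphere: str | None = None
    allow_disconnected: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex triples")
        if self.n_vertices == 0 or self.n_faces == 0:
            raise ValueError("mesh must have at least one vertex and one face")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValueError(
                f"face indices must lie in [0, {self.n_vertices}); "
                f"found range [{self.faces.min()}, {self.faces.max()}]"
            )
        areas = _face_areas(self.vertices, self.faces)
        edge = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        scale = np.linalg.norm(edge, axis=1) ** 2
        bad = np.flatnonzero(areas <= 1e-12 * np.maximum(scale, 1e-300))
        if bad.size:
            raise DegenerateFaceError(
                f"{bad.size} zero-area face(s), first at face index {bad[0]}"
            )
        if not self.allow_disconnected and not self.is_connected():
            raise ValueError(
                "mesh is not edge-connected; pass allow_disconnected=True "
                "to permit multiple components"
            )

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def face_areas(self) -> np.ndarray:
        """Area of every triangle, mm^2."""
        return _face_areas(self.vertices, self.faces)

    @property
    def surface_area(self) -> float:
        """Total surface area, mm^2."""
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) pairs, i < j."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_adjacency(self) -> sp.csr_matrix:
        """Boolean vertex-adjacency matrix (symmetric, no self-loops)."""
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e), dtype=bool)
        adj = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (adj + adj.T).tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.vertex_adjacency(), directed=False)
        return n_comp == 1


@dataclass
class SurfaceMap:
    """One scalar per vertex plus a binary cortex mask.

    ``values`` are in mm for thickness maps and unitless for statistics;
    ``mask`` flags the vertices carrying valid cortical measurements
    (1 = cortex, 0 = medial wall / excluded).
    """

    values: np.ndarray
    mask: np.ndarray
    mesh: TriangleMesh | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.mask = np.asarray(self.mask).ravel().astype(bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal length")
        if self.mesh is not None and len(self.values) != self.mesh.n_vertices:
            raise ValueError(
                f"map length {len(self.values)} does not match mesh "
                f"vertex count {self.mesh.n_vertices}"
            )
        if not self.mask.any():
            raise ValueError("mask must flag at least one vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    @classmethod
    def full(cls, mesh: TriangleMesh, values: np.ndarray, name: str | None = None) -> "SurfaceMap":
        """A map with an all-cortex mask."""
        return cls(values=values, mask=np.ones(mesh.n_vertices, bool), mesh=mesh, name=name)


@dataclass(frozen=True)
class MeshCluster:
    """An edge-connected set of vertices with its total surface area (mm^2)."""

    vertex_indices: tuple[int, ...]
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("cluster area must be positive")

    @property
    def size(self) -> int:
        return len(self.vertex_indices)


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Geodesic icosphere with ``10 * 4**s + 2`` vertices, every one at ``radius``.

    Serves as the synthetic stand-in for a cortical template surface.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(tm.vertices, dtype=np.float64)
    # re-normalize so every vertex sits exactly on the sphere before scaling
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return TriangleMesh(
        vertices=verts,
        faces=np.asarray(tm.faces, dtype=np.int64),
        name=f"icosphere{subdivisions}",
    )


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric (one-third) lumped vertex areas, mm^2.

    Each vertex receives one third of the area of every incident triangle,
    so the per-vertex areas sum exactly to the mesh surface area.  These are
    the lumped mass weights used by the Laplace-Beltrami discretization.
    """
    areas = mesh.face_areas()
    out = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(out, mesh.faces[:, c], areas / 3.0)
    return out


def mesh_clusters(mesh: TriangleMesh, vertex_subset: np.ndarray) -> list[MeshCluster]:
    """Maximal edge-connected components of ``vertex_subset``, largest area first.

    The components partition the subset; each cluster's area is the sum of the
    barycentric vertex areas of its members.  An empty subset yields an empty
    list.  Ties in area break on the smallest member vertex index.
    """
    subset = np.unique(np.asarray(vertex_subset, dtype=np.int64).ravel())
    if subset.size == 0:
        return []
    if subset.min() < 0 or subset.max() >= mesh.n_vertices:
        raise ValueError("vertex_subset contains out-of-range indices")
    adj = mesh.vertex_adjacency()[subset][:, subset]
    n_comp, labels = connected_components(adj, directed=False)
    varea = vertex_areas(mesh)
    clusters = []
    for c in range(n_comp):
        members = subset[labels == c]
        clusters.append(
            MeshCluster(
                vertex_indices=tuple(int(v) for v in members),
                area=float(varea[members].sum()),
            )
        )
    clusters.sort(key=lambda cl: (-cl.area, cl.vertex_indices[0]))
    return clusters
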