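"""Template source space: icosphere hemispheres and mesh geodesics.

The source space used throughout the package is a surrogate for a
template cortical surface: two triangulated icospheres (one per
hemisphere) whose vertices are the candidate dipole positions.  All
spatial error metrics are geodesic distances along the mesh edge graph,
so the mesh carries its edge graph and hemisphere labels explicitly.
Coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "Mesh",
    "build_icosphere",
    "build_template_space",
    "geodesic_distances",
]

LEFT = 0
RIGHT = 1


@dataclass
class Mesh:
    """Triangulated source-space mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    triangles : (F, 3) int array
        Vertex-index triples.
    hemisphere : (V,) int array
        Hemisphere label per vertex, ``0`` = left, ``1`` = right.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray
    _adjacency: csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int64)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) index array."""
        t = self.triangles
        pairs = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse edge-length-weighted adjacency matrix."""
        if self._adjacency is None:
            e = self.edges()
            w = np.linalg.norm(
                self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
            )
            n = self.n_vertices
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            data = np.concatenate([w, w])
            self._adjacency = csr_matrix((data, (rows, cols)), shape=(n, n))
        return self._adjacency

    def hemisphere_vertices(self, hemi: int) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def n_components(self) -> int:
        return connected_components(self.adjacency(), directed=False)[0]

    def to_hdf5(self, group) -> None:
        group.create_dataset("vertices", data=self.vertices)
        group.create_dataset("triangles", data=self.triangles)
        group.create_dataset("hemisphere", data=self.hemisphere)

    @classmethod
    def from_hdf5(cls, group) -> "Mesh":
        return cls(
            vertices=group["vertices"][()],
            triangles=group["triangles"][()],
            hemisphere=group["hemisphere"][()],
        )

    def to_off(self) -> str:
        """Export to OFF text format for external inspection."""
        lines = ["OFF", f"{self.n_vertices} {len(self.triangles)} 0"]
        lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in self.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in self.triangles]
        return "\n".join(lines) + "\n"


# regular icosahedron with circumradius 1
def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def build_icosphere(subdivisions: int, radius: float = 70.0) -> Mesh:
    """Build a geodesic icosphere by recursive edge-midpoint subdivision.

    Each subdivision level splits every triangle into four; the vertex
    count is ``10 * 4**s + 2`` and every vertex sits at ``radius`` from
    the origin.

    Parameters
    ----------
    subdivisions : int
        Number of subdivision rounds, ``0 <= s <= 7``.
    radius : float
        Sphere radius in mm, strictly positive.
    """
    if subdivisions < 0 or subdivisions > 7:
        raise ValueError("subdivisions must be in [0, 7]")
    if radius <= 0:
        raise ValueError("radius must be positive")

    verts, faces = _icosahedron()
    verts = list(verts)
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = midpoint_cache.get(key)
        if idx is None:
            m = verts[i] + verts[j]
            m /= np.linalg.norm(m)
            verts.append(m)
            idx = len(verts) - 1
            midpoint_cache[key] = idx
        return idx

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=np.int64)
        midpoint_cache.clear()

    vertices = np.asarray(verts) * radius
    return Mesh(vertices, faces, np.zeros(len(vertices), dtype=np.int64))


def build_template_space(
    subdivisions: int = 4,
    radius: float = 70.0,
    hemisphere_gap: float = 60.0,
) -> Mesh:
    """Two-hemisphere template source space.

    Two icosphere copies are offset laterally (along x) by
    ``hemisphere_gap`` (center-to-center); no cross-hemisphere edges are
    created, so the edge graph has exactly two connected components even
    for gap 0.  Left hemisphere is shifted toward -x.
    """
    hemi = build_icosphere(subdivisions, radius)
    n = hemi.n_vertices
    shift = np.array([hemisphere_gap / 2.0, 0.0, 0.0])
    vertices = np.vstack([hemi.vertices - shift, hemi.vertices + shift])
    triangles = np.vstack([hemi.triangles, hemi.triangles + n])
    labels = np.concatenate(
        [np.full(n, LEFT, dtype=np.int64), np.full(n, RIGHT, dtype=np.int64)]
    )
    return Mesh(vertices, triangles, labels)


def geodesic_distances(mesh: Mesh, source_vertex: int | np.ndarray) -> np.ndarray:
    """Shortest-path distance (mm) from source vertex/vertices to all vertices.

    Dijkstra on the edge-length-weighted graph; vertices in the other
    hemisphere are unreachable and get ``inf``.  With an array argument
    the result has one row per source vertex.
    """
    single = np.isscalar(source_vertex)
    idx = np.atleast_1d(np.asarray(source_vertex, dtype=np.int64))
    if idx.min() < 0 or idx.max() >= mesh.n_vertices:
        raise IndexError("source vertex out of range")
    d = dijkstra(mesh.adjacency(), directed=False, indices=idx)
    return d[0] if single else d
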