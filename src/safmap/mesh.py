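"""Triangular surface meshes representing the cortical grey/white interface.

A :class:`SurfaceMesh` is a 2-manifold patch: every undirected edge is shared
by at most two triangles.  Vertex adjacency (the 1-ring) is the neighbourhood
used by the surface-based phase-map smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurfaceMesh"]


@dataclass
class SurfaceMesh:
    """A triangulated cortical surface patch.

    Parameters
    ----------
    vertices
        ``(V, 3)`` float array of vertex coordinates in mm.
    triangles
        ``(T, 3)`` int array of vertex index triples with consistent winding
        (normals point from white matter into the cortex).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _neighbors: list | None = field(default=None, repr=False, compare=False)
    _vertex_normals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (V, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be a (T, 3) array")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle indices out of range")
        edges = self.edges()
        if len(edges):
            _, counts = np.unique(edges, axis=0, return_counts=True)
            if counts.max() > 2:
                raise ValueError("mesh is not a 2-manifold patch (edge in >2 triangles)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Undirected edges as a sorted ``(E, 2)`` array (with duplicates)."""
        if not self.triangles.size:
            return np.empty((0, 2), dtype=np.int64)
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return np.sort(e, axis=1)

    @property
    def neighbors(self) -> list:
        """Per-vertex 1-ring neighbour indices (sorted arrays, symmetric)."""
        if self._neighbors is None:
            nbr: list[set] = [set() for _ in range(self.n_vertices)]
            for a, b in np.unique(self.edges(), axis=0):
                nbr[a].add(b)
                nbr[b].add(a)
            self._neighbors = [np.array(sorted(s), dtype=np.int64) for s in nbr]
        return self._neighbors

    @property
    def triangle_normals(self) -> np.ndarray:
        """Unit normals per triangle, following the winding order."""
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        if self._vertex_normals is None:
            v = self.vertices
            t = self.triangles
            fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
            vn = np.zeros_like(v)
            for k in range(3):
                np.add.at(vn, t[:, k], fn)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._vertex_normals = vn / norm
        return self._vertex_normals

    @property
    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)
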