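"""Assigning streamlines to ordered sub-area pairs on the cortical surface.

A streamline connects two cortical sub-areas if it terminates within both:
for each end, the first (respectively last) streamline point lying inside the
cortical ribbon is located, the nearest triangle of the grey/white interface
mesh is found, and the connection end resolves to the sub-area whose vertex
set contains *all three* of that triangle's vertices (the subset rule, which
rejects terminations straddling a border).  Streamlines with more than 80 %
of their length running inside the cortex are removed beforehand to avoid
bias from intracortical pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh
from .retinotopy import SubAreaParcellation
from .tracking import Tractogram, streamline_length

__all__ = [
    "CorticalRibbon",
    "Assignment",
    "intracortical_fraction",
    "locate_end_vertices",
    "assign_connection",
    "assign_tractogram",
    "INTRACORTICAL_MAX_FRACTION",
]

#: Streamlines with a larger intracortical length fraction are rejected.
INTRACORTICAL_MAX_FRACTION = 0.8


def _closest_point_on_triangles(points: np.ndarray, tri_pts: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (``tri_pts``: (N,3,3)) to each point (N,3)."""
    a, b, c = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        result[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)  # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)  # vertex C
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge AB
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge AC
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))  # edge BC
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    interior = a + v[:, None] * ab + w[:, None] * ac
    result[~done] = interior[~done]
    return result


@dataclass
class CorticalRibbon:
    """The cortical shell above the grey/white interface mesh.

    The ribbon is modelled as a constant-``thickness`` (mm) offset of the
    inner surface along its normals.  A point is inside the cortex when its
    signed distance along the nearest inner-triangle normal lies in
    ``[0, thickness]`` (and the point is not laterally far from that
    triangle).  Nearest-triangle ties are broken by the lowest triangle
    index, which makes endpoint resolution deterministic.
    """

    inner: SurfaceMesh
    thickness: float = 2.0
    n_candidates: int = 5
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _tri_radius: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.inner.triangle_centroids)
        return self._tree

    @property
    def tri_radius(self) -> float:
        """Max centroid-to-vertex distance; bounds |centroid dist - true dist|."""
        if self._tri_radius is None:
            c = self.inner.triangle_centroids
            v = self.inner.vertices[self.inner.triangles]
            self._tri_radius = float(np.linalg.norm(v - c[:, None, :], axis=2).max())
        return self._tri_radius

    def nearest_triangle(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest inner-surface triangle per point.

        Returns ``(triangle_index, distance, closest_point)``; candidate
        triangles come from a centroid k-d tree (k nearest centroids), exact
        point-triangle distances decide, ties go to the lowest triangle index.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(self.n_candidates, self.inner.n_triangles)
        _, cand = self.tree.query(pts, k=k)
        cand = np.atleast_2d(cand)
        if cand.ndim == 1:
            cand = cand[:, None]
        flat_tri = self.inner.vertices[self.inner.triangles[cand.ravel()]]
        flat_pts = np.repeat(pts, k, axis=0)
        closest = _closest_point_on_triangles(flat_pts, flat_tri).reshape(len(pts), k, 3)
        dist = np.linalg.norm(closest - pts[:, None, :], axis=2)
        # lexicographic (rounded distance, triangle index): lowest index wins ties
        dr = np.round(dist, 9)
        at_min = dr == dr.min(axis=1, keepdims=True)
        masked_idx = np.where(at_min, cand, np.iinfo(np.int64).max)
        chosen = masked_idx.min(axis=1)
        best = np.argmax(cand == chosen[:, None], axis=1)
        rows = np.arange(len(pts))
        return cand[rows, best], dist[rows, best], closest[rows, best]

    def signed_height(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed distance along the nearest-triangle normal, plus 3-D distance."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tri, dist, closest = self.nearest_triangle(pts)
        normals = self.inner.triangle_normals[tri]
        h = np.einsum("ij,ij->i", pts - closest, normals)
        return h, dist

    def inside_cortex(self, points: np.ndarray) -> np.ndarray:
        """Boolean per point: within the [0, thickness] band above the surface.

        A k-d-tree prefilter discards points whose distance to the nearest
        triangle centroid already exceeds ``thickness + tri_radius`` (they
        cannot lie in the band); the exact nearest-triangle test runs only on
        the survivors.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d_centroid, _ = self.tree.query(pts)
        out = np.zeros(len(pts), dtype=bool)
        near = d_centroid <= self.thickness + self.tri_radius + 1e-6
        if near.any():
            h, dist = self.signed_height(pts[near])
            eps = 1e-9
            out[near] = (
                (h >= -eps) & (h <= self.thickness + eps) & (dist <= self.thickness + 1e-6)
            )
        return out


@dataclass
class Assignment:
    """Outcome of mapping one streamline onto the parcellation."""

    streamline_id: int
    status: str  # 'accepted' or a rejection reason
    subarea_pair: tuple | None = None  # (i, j) with i <= j
    end_vertices: tuple | None = None  # two 3-tuples of vertex indices
    length_mm: float = np.nan

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def intracortical_fraction(streamline: np.ndarray, ribbon: CorticalRibbon) -> float:
    """Fraction of streamline arc length running inside the cortical ribbon.

    Each segment counts as intracortical when its midpoint lies between the
    inner and outer surfaces.  Streamlines with fraction > 0.8 are rejected
    downstream.
    """
    p = np.asarray(streamline, dtype=float)
    seg = np.diff(p, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = seglen.sum()
    if len(p) < 2 or total <= 0:
        raise ValueError("zero-length streamline")
    mid = 0.5 * (p[:-1] + p[1:])
    inside = ribbon.inside_cortex(mid)
    return float(seglen[inside].sum() / total)


def locate_end_vertices(
    streamline: np.ndarray,
    ribbon: CorticalRibbon,
    tolerance: float = 2.0,
) -> tuple:
    """Surrounding vertex triples of the two streamline terminations.

    The termination of each end is the first (respectively last) streamline
    point inside the cortex; its surrounding vertices are the three vertices
    of the nearest inner-surface triangle.  An end is unresolved (``None``)
    when no point of the streamline lies in the cortex or the
    nearest-triangle distance exceeds ``tolerance`` (mm).
    """
    p = np.asarray(streamline, dtype=float)
    inside = ribbon.inside_cortex(p)
    if not inside.any():
        return None, None
    idx = np.where(inside)[0]
    ends = p[[idx[0], idx[-1]]]
    tri, dist, _ = ribbon.nearest_triangle(ends)
    out = []
    for t, d in zip(tri, dist):
        out.append(tuple(int(v) for v in ribbon.inner.triangles[t]) if d <= tolerance else None)
    return tuple(out)


def assign_connection(
    streamline_id: int,
    streamline: np.ndarray,
    ribbon: CorticalRibbon,
    parcellation: SubAreaParcellation,
    tolerance: float = 2.0,
    max_intracortical: float = INTRACORTICAL_MAX_FRACTION,
) -> Assignment:
    """Assign one streamline to an ordered sub-area pair, or reject it.

    Pipeline per streamline: the intracortical-length filter (> 80 %
    intracortical rejects), termination location, then the subset rule: an
    end resolves to the sub-area containing all three surrounding vertices;
    if no single sub-area does, the streamline is rejected as straddling a
    border.  Accepted pairs are normalised so ``i <= j``, making assignment
    invariant to reversing the streamline's point order.
    """
    length = streamline_length(streamline)
    frac = intracortical_fraction(streamline, ribbon)
    if frac > max_intracortical:
        return Assignment(streamline_id, "intracortical", length_mm=length)
    tri1, tri2 = locate_end_vertices(streamline, ribbon, tolerance)
    if tri1 is None or tri2 is None:
        return Assignment(streamline_id, "unresolved_end", length_mm=length)
    vertex_sub = parcellation.vertex_subarea(ribbon.inner.n_vertices)
    pair = []
    for tri in (tri1, tri2):
        subs = set(int(vertex_sub[v]) for v in tri)
        if len(subs) != 1 or -1 in subs:
            return Assignment(
                streamline_id, "straddles_border", end_vertices=(tri1, tri2), length_mm=length
            )
        pair.append(subs.pop())
    i, j = sorted(pair)
    return Assignment(streamline_id, "accepted", (i, j), (tri1, tri2), length)


def assign_tractogram(
    tractogram: Tractogram,
    ribbon: CorticalRibbon,
    parcellation: SubAreaParcellation,
    tolerance: float = 2.0,
    max_intracortical: float = INTRACORTICAL_MAX_FRACTION,
) -> list:
    """Assign every streamline of a tractogram; returns a list of Assignments.

    Vectorises the inside-cortex classification over all points of all
    streamlines at once, which is what makes whole-tractogram assignment
    affordable on meshes with thousands of triangles.
    """
    vertex_sub = parcellation.vertex_subarea(ribbon.inner.n_vertices)
    streamlines = tractogram.streamlines
    if not streamlines:
        return []
    counts = np.array([len(s) for s in streamlines])
    allpts = np.concatenate(streamlines)
    inside_all = ribbon.inside_cortex(allpts)
    bounds = np.cumsum(counts)[:-1]
    inside_split = np.split(inside_all, bounds)
    results: list = [None] * len(streamlines)

    # Intracortical fraction: classify all segment midpoints in one batch.
    mids = np.concatenate([0.5 * (s[:-1] + s[1:]) for s in streamlines])
    mid_inside = ribbon.inside_cortex(mids)
    mid_split = np.split(mid_inside, np.cumsum(counts - 1)[:-1])

    # Endpoint terminations for streamlines passing the 80 % filter.
    term_pts = []
    term_sid = []
    fractions = np.empty(len(streamlines))
    lengths = np.empty(len(streamlines))
    for sid, s in enumerate(streamlines):
        seglen = np.linalg.norm(np.diff(s, axis=0), axis=1)
        lengths[sid] = seglen.sum()
        if lengths[sid] <= 0:
            raise ValueError(f"zero-length streamline {sid}")
        fractions[sid] = seglen[mid_split[sid]].sum() / lengths[sid]
        if fractions[sid] > max_intracortical:
            continue
        inside = inside_split[sid]
        if inside.any():
            idx = np.where(inside)[0]
            term_pts.append(s[idx[0]])
            term_pts.append(s[idx[-1]])
            term_sid.append(sid)

    if term_pts:
        tri_idx, dist, _ = ribbon.nearest_triangle(np.asarray(term_pts))
    for sid in range(len(streamlines)):
        if fractions[sid] > max_intracortical:
            results[sid] = Assignment(sid, "intracortical", length_mm=lengths[sid])
    resolved = {}
    for n, sid in enumerate(term_sid):
        tris = []
        for e in (2 * n, 2 * n + 1):
            if dist[e] <= tolerance:
                tris.append(tuple(int(v) for v in ribbon.inner.triangles[tri_idx[e]]))
            else:
                tris.append(None)
        resolved[sid] = tuple(tris)
    for sid in range(len(streamlines)):
        if results[sid] is not None:
            continue
        tris = resolved.get(sid, (None, None))
        if tris[0] is None or tris[1] is None:
            results[sid] = Assignment(sid, "unresolved_end", length_mm=lengths[sid])
            continue
        pair = []
        reject = False
        for tri in tris:
            subs = set(int(vertex_sub[v]) for v in tri)
            if len(subs) != 1 or -1 in subs:
                reject = True
                break
            pair.append(subs.pop())
        if reject:
            results[sid] = Assignment(
                sid, "straddles_border", end_vertices=tris, length_mm=lengths[sid]
            )
        else:
            i, j = sorted(pair)
            results[sid] = Assignment(sid, "accepted", (i, j), tris, lengths[sid])
    return results
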