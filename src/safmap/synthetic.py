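"""Synthetic cortical geometry, retinotopy, tractograms and ODF fields.

Everything the pipeline consumes can be generated here under explicit seeds:

* a folded rectangular sheet standing in for the grey/white interface, with
  sinusoidal folds emulating gyri and sulci (fold ridges run orthogonal to
  the eccentricity axis, so termination localisation is probed on curved
  cortex);
* three parallel area bands V1 | V2 | V3 sharing borders, with a smooth
  eccentricity gradient along the sheet, polar angle sweeping the hemifield
  within each band with mirror reversals at the shared borders, phase noise,
  and an SNR map with a controllable unreliable fraction;
* planted tractograms of U-shaped arcs whose ends terminate just inside the
  cortex over chosen sub-area pairs, with per-streamline ground truth
  recorded for recovery tests.  Non-retinotopic and intra-area noise
  streamlines connect anatomically adjacent but retinotopically
  non-corresponding sub-areas, emulating the endpoint misassignment that
  gyral bias produces in real data;
* a fibre-ODF amplitude field with amplitudes peaked along planted bundle
  tangents, an isotropic baseline within the white-matter slab, and the
  white-matter mask defined by amplitudes exceeding 0.1.

The white matter lies below the sheet (negative normal direction), the
cortical ribbon above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh
from .retinotopy import AreaLabels, RetinotopicMap, SubAreaParcellation, N_SUBAREAS
from .tracking import Tractogram, streamline_length
from .volume import OdfField, make_sphere_directions

__all__ = [
    "PlantedTruth",
    "make_mesh",
    "make_area_labels",
    "make_retinotopy",
    "make_planted_tractogram",
    "make_odf_field",
    "cortical_seed_mask",
]

#: Minimum eccentricity mapped by the emulated fMRI experiment (degrees).
ECC_RANGE = (0.89, 6.0)


@dataclass
class PlantedTruth:
    """Ground truth for a planted tractogram.

    ``pairs[k]`` is the intended (normalised) sub-area pair of streamline
    ``k``; ``kinds[k]`` is 'retinotopic', 'nonretinotopic' or 'intra'.
    """

    pairs: list
    kinds: list
    retinotopic_fraction: float

    def __post_init__(self) -> None:
        for p in self.pairs:
            i, j = p
            if not (0 <= i < N_SUBAREAS and 0 <= j < N_SUBAREAS):
                raise ValueError(f"planted pair {p} out of sub-area range")


def make_mesh(
    n_rows: int,
    n_cols: int,
    fold_amplitude: float,
    seed: int,
    spacing: float = 1.0,
    fold_wavelength: float = 10.0,
    jitter: float = 0.0,
) -> SurfaceMesh:
    """Folded rectangular sheet mesh emulating a cortical patch.

    The sheet spans ``n_cols`` columns along x (the eccentricity axis) and
    ``n_rows`` rows along y (the area/polar-angle axis), at ``spacing`` mm.
    Height is ``fold_amplitude * sin(2 pi x / fold_wavelength)``: fold ridges
    (gyral crowns) run along y, orthogonal to the eccentricity axis.
    Optional in-plane ``jitter`` (fraction of spacing) breaks the regular
    grid; the result is deterministic for a given seed.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("need n_rows >= 4 and n_cols >= 4")
    rng = np.random.default_rng(seed)
    x, y = np.meshgrid(
        np.arange(n_cols) * spacing, np.arange(n_rows) * spacing, indexing="xy"
    )
    x = x.astype(float)
    y = y.astype(float)
    if jitter > 0:
        x[1:-1, 1:-1] += rng.uniform(-jitter, jitter, x[1:-1, 1:-1].shape) * spacing
        y[1:-1, 1:-1] += rng.uniform(-jitter, jitter, y[1:-1, 1:-1].shape) * spacing
    z = fold_amplitude * np.sin(2.0 * np.pi * x / fold_wavelength)
    vertices = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    tris = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            v00 = r * n_cols + c
            v01 = v00 + 1
            v10 = v00 + n_cols
            v11 = v10 + 1
            # winding gives normals along +z (towards the cortex)
            tris.append([v00, v01, v11])
            tris.append([v00, v11, v10])
    return SurfaceMesh(vertices=vertices, triangles=np.array(tris, dtype=np.int64))


def make_area_labels(mesh: SurfaceMesh) -> AreaLabels:
    """Three parallel area bands V1 | V2 | V3 along the y axis.

    Vertices are split at the terciles of the y range; the bands share
    borders through mesh edges while the label sets stay disjoint.
    """
    y = mesh.vertices[:, 1]
    lo, hi = y.min(), y.max()
    t = (y - lo) / (hi - lo) if hi > lo else np.zeros_like(y)
    band = np.minimum((t * 3).astype(np.int64), 2)
    idx = np.arange(mesh.n_vertices)
    return AreaLabels(v1=idx[band == 0], v2=idx[band == 1], v3=idx[band == 2])


def make_retinotopy(
    mesh: SurfaceMesh,
    labels: AreaLabels,
    noise_sd: float,
    low_snr_fraction: float,
    seed: int,
    ecc_range: tuple = ECC_RANGE,
    snr_threshold: float = 5.0,
) -> RetinotopicMap:
    """Retinotopic phase maps with additive noise and an SNR map.

    Eccentricity increases linearly along x over ``ecc_range`` (default
    0.89-6 degrees of visual angle, the mapped range of the emulated
    experiment).  Polar angle sweeps 90 deg (upper vertical meridian) to
    270 deg (lower vertical meridian) across each area band, with mirror
    reversals at the shared borders, so each area contains both an upper
    (ventral) and a lower (dorsal) hemifield half.  Independent Gaussian
    phase noise of ``noise_sd`` degrees is added to both maps.  Exactly
    ``floor(low_snr_fraction * V)`` randomly chosen vertices receive
    ``snr < snr_threshold``; all others receive ``snr >= snr_threshold``.
    """
    if not 0 <= low_snr_fraction < 1:
        raise ValueError("low_snr_fraction must lie in [0, 1)")
    covered = np.zeros(mesh.n_vertices, dtype=bool)
    covered[labels.union()] = True
    if not covered.all():
        raise ValueError("area labels must cover every mesh vertex")
    rng = np.random.default_rng(seed)
    x = mesh.vertices[:, 0]
    y = mesh.vertices[:, 1]
    lo, hi = ecc_range
    ecc = lo + (hi - lo) * (x - x.min()) / (x.max() - x.min())

    polar = np.empty(mesh.n_vertices)
    for a, verts in enumerate(labels.areas):
        ya = y[verts]
        span = ya.max() - ya.min()
        t = (ya - ya.min()) / span if span > 0 else np.zeros_like(ya)
        if a % 2 == 0:  # V1 and V3: 90 -> 270
            polar[verts] = 90.0 + 180.0 * t
        else:  # V2 reversed: continuous at both borders
            polar[verts] = 270.0 - 180.0 * t

    if noise_sd > 0:
        ecc = np.maximum(0.0, ecc + rng.normal(0.0, noise_sd, mesh.n_vertices))
        polar = np.mod(polar + rng.normal(0.0, noise_sd, mesh.n_vertices), 360.0)

    n_low = int(np.floor(low_snr_fraction * mesh.n_vertices))
    snr = rng.uniform(snr_threshold + 1.0, 4.0 * snr_threshold, mesh.n_vertices)
    low_idx = rng.choice(mesh.n_vertices, size=n_low, replace=False)
    snr[low_idx] = rng.uniform(0.2 * snr_threshold, 0.9 * snr_threshold, n_low)
    return RetinotopicMap(eccentricity=ecc, polar_angle=polar, snr=snr)


def _u_arc(p0: np.ndarray, p1: np.ndarray, dip: np.ndarray, depth: float, step: float) -> np.ndarray:
    """U-shaped quadratic arc from p0 to p1 dipping ``depth/2`` along ``-dip``."""
    ctrl = 0.5 * (p0 + p1) - depth * dip
    t = np.linspace(0.0, 1.0, 256)[:, None]
    dense = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_pts = max(int(np.round(total / step)) + 1, 3)
    targets = np.linspace(0.0, total, n_pts)
    out = np.empty((n_pts, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, arc, dense[:, k])
    return out


def _full_triangles(mesh: SurfaceMesh, parcellation: SubAreaParcellation) -> list:
    """Per sub-area: triangles whose three vertices all lie in that sub-area."""
    vsub = parcellation.vertex_subarea(mesh.n_vertices)
    tri_sub = vsub[mesh.triangles]
    out = []
    for s in range(N_SUBAREAS):
        full = np.where((tri_sub == s).all(axis=1))[0]
        out.append(full)
    return out


# Anatomically adjacent sub-area pairs used for noise streamlines, in local
# (0-5) numbering: same-hemifield eccentricity neighbours and the
# cross-hemifield pair at equal eccentricity.
_ADJ_SAME_HEMI = ((0, 1), (1, 2), (3, 4), (4, 5))
_ADJ_CROSS_HEMI = ((0, 3), (1, 4), (2, 5))


def make_planted_tractogram(
    parcellation: SubAreaParcellation,
    mesh: SurfaceMesh,
    n_retinotopic: int,
    n_nonretinotopic: int,
    n_intra: int,
    seed: int,
    thickness: float = 2.0,
    step: float = 0.2,
    area_pairs: tuple = ((0, 1), (1, 2), (0, 2)),
    endpoint_height: float = 0.4,
    min_depth: float = 1.5,
) -> tuple[Tractogram, PlantedTruth]:
    """Plant U-fibre streamlines between known sub-area pairs.

    Retinotopic streamlines connect inter-area sub-areas with the same local
    number; non-retinotopic ones connect anatomically adjacent but
    retinotopically mismatched inter-area sub-areas (local numbers differing
    by one eccentricity bin); intra-area ones connect adjacent sub-areas of
    one area.  Both ends terminate ``endpoint_height`` mm above a triangle
    wholly contained in the intended sub-area (i.e. just inside the cortex);
    the arc dips below the surface into the white matter.  All lengths fall
    in 3-120 mm; the intended pair of every streamline is recorded.
    """
    if min(n_retinotopic, n_nonretinotopic, n_intra) < 0:
        raise ValueError("streamline counts must be non-negative")
    rng = np.random.default_rng(seed)
    full_tris = _full_triangles(mesh, parcellation)
    normals = mesh.triangle_normals
    centroids = mesh.triangle_centroids
    height = _surface_height(mesh)

    def endpoint(sub: int) -> np.ndarray:
        tris = full_tris[sub]
        if len(tris) == 0:
            raise ValueError(
                f"sub-area {sub} has no wholly contained triangle (empty sub-area?)"
            )
        t = tris[rng.integers(len(tris))]
        return centroids[t] + endpoint_height * normals[t], normals[t]

    def submerge(pts: np.ndarray, margin: float = 0.8, taper: float = 1.5) -> np.ndarray:
        """Push interior arc points below the local surface into white matter.

        U-fibres follow the white matter under the folds; only the terminal
        ``taper`` mm at each end are allowed to ascend into the cortex.
        """
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        interior = (s > taper) & (s[-1] - s > taper)
        zsurf = height(pts[interior, 0], pts[interior, 1])
        cap = np.where(np.isnan(zsurf), pts[interior, 2], zsurf - margin)
        out = pts.copy()
        out[interior, 2] = np.minimum(out[interior, 2], cap)
        return out

    def plant(i: int, j: int) -> np.ndarray:
        (a, na), (b, nb) = endpoint(i), endpoint(j)
        dip = na + nb
        dip /= np.linalg.norm(dip)
        depth = max(min_depth, 0.35 * float(np.linalg.norm(b - a)))
        for _ in range(6):
            pts = submerge(_u_arc(a, b, dip, depth, step))
            if streamline_length(pts) >= 3.0:
                return pts
            depth *= 1.6
        return pts

    streamlines: list = []
    pairs: list = []
    kinds: list = []

    for _ in range(n_retinotopic):
        pa, pb = area_pairs[rng.integers(len(area_pairs))]
        k = int(rng.integers(6))
        i, j = 6 * pa + k, 6 * pb + k
        streamlines.append(plant(i, j))
        pairs.append((min(i, j), max(i, j)))
        kinds.append("retinotopic")

    for _ in range(n_nonretinotopic):
        pa, pb = area_pairs[rng.integers(len(area_pairs))]
        la, lb = _ADJ_SAME_HEMI[rng.integers(len(_ADJ_SAME_HEMI))]
        if rng.random() < 0.5:
            la, lb = lb, la
        i, j = 6 * pa + la, 6 * pb + lb
        streamlines.append(plant(i, j))
        pairs.append((min(i, j), max(i, j)))
        kinds.append("nonretinotopic")

    intra_pairs = _ADJ_SAME_HEMI + _ADJ_CROSS_HEMI
    for _ in range(n_intra):
        a = int(rng.integers(3))
        la, lb = intra_pairs[rng.integers(len(intra_pairs))]
        i, j = 6 * a + la, 6 * a + lb
        streamlines.append(plant(i, j))
        pairs.append((min(i, j), max(i, j)))
        kinds.append("intra")

    total = len(streamlines)
    frac = n_retinotopic / total if total else 0.0
    tractogram = Tractogram(streamlines=streamlines, provenance="planted")
    return tractogram, PlantedTruth(pairs=pairs, kinds=kinds, retinotopic_fraction=frac)


def _surface_height(mesh: SurfaceMesh):
    """(x, y) -> surface z interpolator over the sheet (NaN outside)."""
    return LinearNDInterpolator(mesh.vertices[:, :2], mesh.vertices[:, 2])


def make_odf_field(
    mesh: SurfaceMesh,
    bundles: list,
    voxel_size: float,
    seed: int,
    parcellation: SubAreaParcellation | None = None,
    base_amplitude: float = 0.12,
    peak_amplitude: float = 1.0,
    ambient_amplitude: float = 0.01,
    concentration: float = 30.0,
    tube_radius: float = 1.2,
    wm_depth: float = 6.0,
    thickness: float = 2.0,
    pad: float = 2.0,
    subdivisions: int = 3,
    amplitude_threshold: float = 0.1,
) -> OdfField:
    """Fibre-ODF amplitude field with bundles planted between sub-area pairs.

    The grid covers the sheet laterally (plus ``pad`` mm) and vertically from
    ``wm_depth`` mm below the deepest surface point to above the cortical
    ribbon.  Voxels beneath the outer (pial) surface get an isotropic
    ``base_amplitude``; voxels above it an ``ambient_amplitude``.  For each
    bundle (a pair of global sub-area indices, resolved through
    ``parcellation``), a U-shaped tube of radius ``tube_radius`` mm adds a
    Watson-like amplitude lobe ``peak * |d . t|^concentration`` around the
    local tangent ``t``.  The white-matter mask is, by construction, true
    exactly where the per-voxel maximum amplitude exceeds
    ``amplitude_threshold``.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if bundles and parcellation is None:
        raise ValueError("bundles need a parcellation to resolve sub-area indices")
    del seed  # geometry is fully deterministic; seed reserved for noise variants
    directions = make_sphere_directions(subdivisions)
    v = mesh.vertices
    origin = np.array(
        [v[:, 0].min() - pad, v[:, 1].min() - pad, v[:, 2].min() - wm_depth]
    )
    top = np.array([v[:, 0].max() + pad, v[:, 1].max() + pad, v[:, 2].max() + thickness + pad])
    shape = np.maximum(np.ceil((top - origin) / voxel_size).astype(int) + 1, 2)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = origin

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel_size + origin
    zsurf = _surface_height(mesh)(centers[:, 0], centers[:, 1])
    below_pial = np.where(np.isnan(zsurf), False, centers[:, 2] <= zsurf + thickness)
    iso = np.where(below_pial, base_amplitude, ambient_amplitude).astype(np.float32)
    amplitudes = np.broadcast_to(
        iso[:, None], (len(centers), len(directions))
    ).copy()

    if bundles:
        full_tris = _full_triangles(mesh, parcellation)
        normals = mesh.triangle_normals
        centroids = mesh.triangle_centroids

        def anchor(sub: int) -> tuple[np.ndarray, np.ndarray]:
            if not 0 <= int(sub) < N_SUBAREAS:
                raise ValueError(f"bundle references unknown sub-area {sub}")
            tris = full_tris[int(sub)]
            if len(tris) == 0:
                raise ValueError(f"sub-area {sub} has no wholly contained triangle")
            pos = centroids[tris].mean(axis=0)
            t = tris[np.argmin(np.linalg.norm(centroids[tris] - pos, axis=1))]
            return centroids[t] + 0.4 * normals[t], normals[t]

        best_d2 = np.full(len(centers), np.inf)
        tangent = np.zeros((len(centers), 3))
        for i, j in bundles:
            (a, na), (b, nb) = anchor(i), anchor(j)
            dip = na + nb
            dip /= np.linalg.norm(dip)
            depth = max(1.5, 0.35 * float(np.linalg.norm(b - a)))
            path = _u_arc(a, b, dip, depth, voxel_size / 2.0)
            tang = np.gradient(path, axis=0)
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            tree = cKDTree(path)
            d, nearest = tree.query(centers, distance_upper_bound=tube_radius)
            hit = np.isfinite(d)
            closer = hit & (d**2 < best_d2)
            best_d2[closer] = d[closer] ** 2
            tangent[closer] = tang[nearest[closer]]
        in_tube = np.isfinite(best_d2)
        if in_tube.any():
            lobe = (
                peak_amplitude
                * np.abs(tangent[in_tube] @ directions.T) ** concentration
            ).astype(np.float32)
            amplitudes[in_tube] += lobe

    amplitudes = amplitudes.reshape(*shape, len(directions))
    return OdfField(
        amplitudes=amplitudes,
        directions=directions,
        affine=affine,
        amplitude_threshold=amplitude_threshold,
    )


def cortical_seed_mask(
    field: OdfField,
    mesh: SurfaceMesh,
    thickness: float = 2.0,
    max_voxels: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Boolean volume of voxels whose centre lies in the cortical ribbon.

    ``max_voxels`` optionally subsamples the mask to bound tractography cost.
    Subsampling is spatially uniform (an even stride through the sorted voxel
    list with a seed-dependent phase) so that seed coverage — and hence the
    null termination distribution — stays spread over the whole sheet rather
    than clustering.
    """
    shape = field.grid_shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centers = field.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    zsurf = _surface_height(mesh)(centers[:, 0], centers[:, 1])
    h = centers[:, 2] - zsurf
    inside = np.where(np.isnan(zsurf), False, (h >= 0) & (h <= thickness))
    mask = inside.reshape(shape)
    n = int(mask.sum())
    if max_voxels is not None and n > max_voxels:
        rng = np.random.default_rng(seed)
        idx = np.argwhere(mask)
        pick = (
            np.floor(np.arange(max_voxels) * n / max_voxels).astype(int)
            + rng.integers(int(np.ceil(n / max_voxels)))
        ) % n
        keep = idx[np.unique(pick)]
        mask = np.zeros(shape, dtype=bool)
        mask[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return mask
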