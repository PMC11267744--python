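"""Probabilistic ODF tractography and isotropic null-distribution tractography.

Both trackers share the same mechanics: bidirectional propagation from a
dense regular grid of seed points (default 4 x 4 x 4 per seed voxel) with a
fixed step size (default 0.2 mm), a per-step curvature cap (default 30 deg
between successive step directions) and a retained-length window (default
3-120 mm).

The ODF tracker samples the next direction with probability proportional to
the trilinearly interpolated ODF amplitude among directions within the
curvature cone and above the amplitude threshold (default 0.1).  The null
tracker draws the next direction uniformly from the same cone and is confined
to the white-matter mask; it captures the length and geometry biases of
streamline propagation in the absence of any fibre orientation information,
and is the basis of the null hypothesis used by the significance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volume import OdfField, sample_trilinear

__all__ = [
    "TrackingParams",
    "Tractogram",
    "streamline_length",
    "seed_points_from_mask",
    "track_odf",
    "track_null",
]


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters.

    Defaults: 0.2 mm steps, 30 deg curvature threshold per step, seed and
    tracking amplitude threshold 0.1, retained lengths 3-120 mm and a
    4 x 4 x 4 seed grid per voxel.
    """

    step_size: float = 0.2
    max_angle: float = 30.0
    amplitude_threshold: float = 0.1
    min_length: float = 3.0
    max_length: float = 120.0
    seeds_per_voxel_axis: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.max_angle < 90:
            raise ValueError("max_angle must lie in (0, 90) degrees")
        if not 0 <= self.min_length < self.max_length:
            raise ValueError("need 0 <= min_length < max_length")
        if self.seeds_per_voxel_axis < 1:
            raise ValueError("seeds_per_voxel_axis must be >= 1")

    @property
    def max_steps(self) -> int:
        return int(np.floor(self.max_length / self.step_size + 1e-9))


@dataclass
class Tractogram:
    """Ordered 3-D point sequences (mm) with provenance 'odf', 'null' or 'planted'."""

    streamlines: list
    provenance: str = "odf"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([streamline_length(s) for s in self.streamlines])


def streamline_length(points: np.ndarray) -> float:
    """Polyline length in mm: the sum of Euclidean segment lengths."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("a streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def seed_points_from_mask(
    seed_mask: np.ndarray, affine: np.ndarray, per_axis: int
) -> np.ndarray:
    """Regular ``per_axis^3`` grid of seed points (mm) inside each masked voxel."""
    seed_mask = np.asarray(seed_mask)
    if seed_mask.ndim == 3:
        voxels = np.argwhere(seed_mask)
    else:
        voxels = np.atleast_2d(np.asarray(seed_mask, dtype=np.int64))
    if len(voxels) == 0:
        raise ValueError("seed mask is empty")
    offs = (np.arange(per_axis) + 0.5) / per_axis - 0.5
    grid = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    vox_pts = (voxels[:, None, :] + grid[None, :, :]).reshape(-1, 3)
    affine = np.asarray(affine, dtype=float)
    return vox_pts @ affine[:3, :3].T + affine[:3, 3]


def _direction_neighbors(directions: np.ndarray, max_angle: float) -> np.ndarray:
    """For each direction, indices of directions within ``max_angle`` (padded -1)."""
    cosmax = np.cos(np.deg2rad(max_angle))
    dots = directions @ directions.T
    rows = [np.where(dots[i] >= cosmax - 1e-12)[0] for i in range(len(directions))]
    k = max(len(r) for r in rows)
    out = np.full((len(directions), k), -1, dtype=np.int64)
    for i, r in enumerate(rows):
        out[i, : len(r)] = r
    return out


def _antipode_map(directions: np.ndarray) -> np.ndarray:
    """Index of the direction closest to the antipode of each direction."""
    tree = cKDTree(directions)
    _, idx = tree.query(-directions)
    return idx


def _categorical_sample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw; rows with zero total weight return -1."""
    totals = weights.sum(axis=1)
    out = np.full(len(weights), -1, dtype=np.int64)
    ok = totals > 0
    if ok.any():
        cum = np.cumsum(weights[ok], axis=1)
        u = rng.random(ok.sum()) * totals[ok]
        out[ok] = (u[:, None] >= cum).sum(axis=1)
    return out


class _WalkRecorder:
    """Accumulates per-step positions of a shrinking active walker set."""

    def __init__(self, n_walkers: int):
        self.n = n_walkers
        self.ids: list[np.ndarray] = []
        self.pts: list[np.ndarray] = []

    def record(self, ids: np.ndarray, pts: np.ndarray) -> None:
        self.ids.append(ids.copy())
        self.pts.append(pts.copy())

    def paths(self) -> list:
        """Per-walker (n_i, 3) arrays in step order (may be empty)."""
        if not self.ids:
            return [np.empty((0, 3)) for _ in range(self.n)]
        ids = np.concatenate(self.ids)
        step = np.concatenate([np.full(len(i), s) for s, i in enumerate(self.ids)])
        pts = np.concatenate(self.pts)
        order = np.lexsort((step, ids))
        ids, pts = ids[order], pts[order]
        counts = np.bincount(ids, minlength=self.n)
        bounds = np.cumsum(counts)[:-1]
        return np.split(pts, bounds)


def _propagate_odf(
    field: OdfField,
    pos0: np.ndarray,
    dir_idx0: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    nbr: np.ndarray,
) -> list:
    """Propagate walkers one-directionally; returns per-walker point arrays."""
    dirs = field.directions
    rec = _WalkRecorder(len(pos0))
    ids = np.arange(len(pos0))
    pos = pos0.copy()
    dir_idx = dir_idx0.copy()
    for _ in range(params.max_steps):
        if len(ids) == 0:
            break
        pos = pos + params.step_size * dirs[dir_idx]
        rec.record(ids, pos)
        cand = nbr[dir_idx]
        amps = field.sample_amplitudes(pos, cand)
        # small epsilon absorbs float32 storage rounding of the threshold value
        amps[amps <= params.amplitude_threshold + 1e-6] = 0.0
        choice = _categorical_sample(amps, rng)
        alive = choice >= 0
        ids, pos = ids[alive], pos[alive]
        dir_idx = cand[alive, choice[alive]]
    return rec.paths()


def _assemble_bidirectional(
    seeds: np.ndarray,
    fwd: list,
    bwd: list,
    params: TrackingParams,
    provenance: str,
) -> Tractogram:
    streamlines = []
    for seed, f, b in zip(seeds, fwd, bwd):
        pts = np.concatenate([b[::-1], seed[None, :], f])
        n_segments = len(pts) - 1
        if n_segments < 1:
            continue
        length = n_segments * params.step_size
        if params.min_length <= length <= params.max_length:
            streamlines.append(pts)
    return Tractogram(streamlines=streamlines, provenance=provenance)


def track_odf(
    field: OdfField,
    seed_mask: np.ndarray,
    params: TrackingParams,
    *,
    seed_batch: int = 4096,
) -> Tractogram:
    """Probabilistic fibre-ODF tractography from a cortical seed mask.

    From each of ``seeds_per_voxel_axis**3`` regularly spaced points per seed
    voxel, an initial direction is drawn with probability proportional to the
    local ODF amplitude (restricted to amplitudes above the threshold; seeds
    with no admissible direction produce nothing).  Propagation is
    bidirectional: the two halves, tracked from the seed along the initial
    direction and its antipode, are concatenated.  At every step the next
    direction is drawn with probability proportional to amplitude among the
    directions within ``max_angle`` of the previous step and above the
    threshold; a walker stops when no direction is admissible (which includes
    leaving the volume, where amplitudes decay to zero).  Streamlines outside
    the retained-length window are discarded.
    """
    seeds = seed_points_from_mask(seed_mask, field.affine, params.seeds_per_voxel_axis)
    rng = np.random.default_rng(params.rng_seed)
    nbr = _direction_neighbors(field.directions, params.max_angle)
    anti = _antipode_map(field.directions)
    all_dirs = np.arange(field.n_directions)

    kept_seeds = []
    fwd_all: list = []
    bwd_all: list = []
    for start in range(0, len(seeds), seed_batch):
        batch = seeds[start : start + seed_batch]
        amps = field.sample_amplitudes(batch, np.broadcast_to(all_dirs, (len(batch), len(all_dirs))))
        amps = amps.copy()
        amps[amps <= params.amplitude_threshold + 1e-6] = 0.0
        d0 = _categorical_sample(amps, rng)
        ok = d0 >= 0
        batch, d0 = batch[ok], d0[ok]
        fwd = _propagate_odf(field, batch, d0, params, rng, nbr)
        bwd = _propagate_odf(field, batch, anti[d0], params, rng, nbr)
        kept_seeds.append(batch)
        fwd_all.extend(fwd)
        bwd_all.extend(bwd)
    kept = np.concatenate(kept_seeds) if kept_seeds else np.empty((0, 3))
    return _assemble_bidirectional(kept, fwd_all, bwd_all, params, "odf")


def _uniform_cone(prev: np.ndarray, max_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Directions drawn uniformly from the cone of half-angle ``max_angle``."""
    n = len(prev)
    z = rng.uniform(np.cos(np.deg2rad(max_angle)), 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    local = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # Orthonormal frame with third axis = prev
    ref = np.where(np.abs(prev[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    u = np.cross(ref, prev)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(prev, u)
    return local[:, 0:1] * u + local[:, 1:2] * v + local[:, 2:3] * prev


def _propagate_null(
    wm_mask: np.ndarray,
    inv_affine: np.ndarray,
    pos0: np.ndarray,
    dir0: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> list:
    maskf = wm_mask.astype(np.float32)
    rec = _WalkRecorder(len(pos0))
    ids = np.arange(len(pos0))
    pos = pos0.copy()
    d = dir0.copy()
    for _ in range(params.max_steps):
        if len(ids) == 0:
            break
        pos = pos + params.step_size * d
        rec.record(ids, pos)
        vox = pos @ inv_affine[:3, :3].T + inv_affine[:3, 3]
        inside = sample_trilinear(maskf, vox) >= 0.5
        ids, pos, d = ids[inside], pos[inside], d[inside]
        d = _uniform_cone(d, params.max_angle, rng)
    return rec.paths()


def track_null(
    wm_mask: np.ndarray,
    affine: np.ndarray,
    seed_mask: np.ndarray,
    params: TrackingParams,
    repeats: int = 10,
) -> list:
    """Isotropic random-walk null tractography, repeated ``repeats`` times.

    Mechanics are identical to :func:`track_odf` except that the next step
    direction is drawn uniformly from the cone within ``max_angle`` of the
    previous direction (the initial direction is uniform on the sphere), and
    propagation is confined to the white-matter mask: a walker terminates on
    the first point whose interpolated mask value falls below 0.5, so null
    terminations sit just outside the mask, in the cortex.  Each repeat uses
    an independent random stream derived from ``params.rng_seed``; the same
    retained-length window is applied before counting.

    Returns a list of ``repeats`` :class:`Tractogram` objects.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    seeds = seed_points_from_mask(seed_mask, affine, params.seeds_per_voxel_axis)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    out = []
    for child in np.random.SeedSequence(params.rng_seed).spawn(int(repeats)):
        rng = np.random.default_rng(child)
        d0 = rng.standard_normal((len(seeds), 3))
        d0 /= np.linalg.norm(d0, axis=1, keepdims=True)
        fwd = _propagate_null(wm_mask, inv, seeds, d0, params, rng)
        bwd = _propagate_null(wm_mask, inv, seeds, -d0, params, rng)
        out.append(_assemble_bidirectional(seeds, fwd, bwd, params, "null"))
    return out
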