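"""Voxel-grid containers: fibre-ODF amplitude fields and boolean masks.

Conventions: 0-based voxel indices, voxel-centre alignment — the affine maps
voxel index ``(i, j, k)`` to the mm coordinate of that voxel's centre.
Scalar volumes and per-direction amplitudes are sampled with trilinear
interpolation; a point is "inside" a boolean mask where the interpolated
value is >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OdfField", "trilinear_corners", "sample_trilinear", "make_sphere_directions"]


def make_sphere_directions(subdivisions: int = 3) -> np.ndarray:
    """Unit direction set from a subdivided icosahedron (642 for level 3)."""
    import trimesh

    return np.asarray(trimesh.creation.icosphere(subdivisions=subdivisions).vertices, float)


def trilinear_corners(voxel_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Corner indices and weights for trilinear interpolation.

    Parameters
    ----------
    voxel_coords
        ``(P, 3)`` continuous voxel coordinates.

    Returns
    -------
    corners : ``(P, 8, 3)`` int array of voxel indices (may be out of range).
    weights : ``(P, 8)`` trilinear weights summing to 1.
    """
    c = np.asarray(voxel_coords, dtype=float)
    base = np.floor(c).astype(np.int64)
    frac = c - base
    offs = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
    )
    corners = base[:, None, :] + offs[None, :, :]
    w = np.where(offs[None, :, :] == 1, frac[:, None, :], 1.0 - frac[:, None, :])
    return corners, w.prod(axis=2)


def sample_trilinear(volume: np.ndarray, voxel_coords: np.ndarray) -> np.ndarray:
    """Trilinearly sample a scalar volume; out-of-range corners count as 0."""
    corners, w = trilinear_corners(voxel_coords)
    shape = np.array(volume.shape[:3])
    valid = np.all((corners >= 0) & (corners < shape), axis=2)
    cc = np.where(valid[:, :, None], corners, 0)
    vals = volume[cc[:, :, 0], cc[:, :, 1], cc[:, :, 2]].astype(float)
    vals[~valid] = 0.0
    return (vals * w).sum(axis=1)


@dataclass
class OdfField:
    """Per-voxel fibre-ODF amplitudes over a fixed unit-sphere direction set.

    ``amplitudes`` has shape ``(X, Y, Z, D)`` for ``D`` directions; the white
    matter mask is true exactly where the per-voxel maximum amplitude exceeds
    ``amplitude_threshold`` (default 0.1).
    """

    amplitudes: np.ndarray
    directions: np.ndarray
    affine: np.ndarray
    amplitude_threshold: float = 0.1
    wm_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float32)
        self.directions = np.asarray(self.directions, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.amplitudes.ndim != 4:
            raise ValueError("amplitudes must have shape (X, Y, Z, D)")
        if self.directions.shape != (self.amplitudes.shape[3], 3):
            raise ValueError("directions must match the amplitude direction axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        computed = np.asarray(self.amplitudes.max(axis=3) > self.amplitude_threshold)
        if self.wm_mask is None:
            self.wm_mask = computed
        else:
            self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
            if not np.array_equal(self.wm_mask, computed):
                raise ValueError(
                    "wm_mask must equal (max amplitude > amplitude_threshold)"
                )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.amplitudes.shape[:3]

    @property
    def n_directions(self) -> int:
        return self.amplitudes.shape[3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxels, dtype=float))
        return v @ self.affine[:3, :3].T + self.affine[:3, 3]

    def sample_amplitudes(self, points: np.ndarray, dir_indices: np.ndarray) -> np.ndarray:
        """Trilinear ODF amplitudes at mm ``points`` for per-point direction sets.

        ``dir_indices`` is ``(P, K)`` (entries < 0 are padding and yield 0);
        returns ``(P, K)``.  Out-of-volume corners contribute 0 amplitude, so
        amplitudes decay to zero at the grid boundary.
        """
        pts = np.atleast_2d(points)
        di = np.atleast_2d(dir_indices)
        corners, w = trilinear_corners(self.world_to_voxel(pts))
        shape = np.array(self.grid_shape)
        valid = np.all((corners >= 0) & (corners < shape), axis=2)
        cc = np.where(valid[:, :, None], corners, 0)
        pad = di < 0
        dd = np.where(pad, 0, di)
        # (P, 8, K) gather, then weight-sum over corners
        vals = self.amplitudes[
            cc[:, :, 0][:, :, None], cc[:, :, 1][:, :, None], cc[:, :, 2][:, :, None], dd[:, None, :]
        ].astype(float)
        vals[~valid] = 0.0
        out = (vals * w[:, :, None]).sum(axis=1)
        out[pad] = 0.0
        return out

    def sample_mask(self, points: np.ndarray) -> np.ndarray:
        """Trilinear white-matter mask values at mm points (inside >= 0.5)."""
        return sample_trilinear(self.wm_mask.astype(np.float32), self.world_to_voxel(points))
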