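"""Retinotopic phase maps: SNR gating, surface smoothing, sub-area segmentation.

Visual areas V1, V2 and V3 each carry a retinotopic map: eccentricity (degrees
of visual angle from fixation) and polar angle (degrees around fixation) vary
smoothly over the cortical sheet.  This module

* computes a per-vertex signal-to-noise ratio from a phase-encoded fMRI
  time-series (stimulus-frequency magnitude over spectrum standard deviation),
* smooths phase maps on the mesh by iterated 1-ring neighbourhood means,
  restricted to vertices whose SNR passes a reliability threshold, and
* segments each visual area into 6 sub-areas: {dorsal, ventral} hemifield
  x 3 eccentricity bins cut at thirds of the normalised eccentricity range,
  yielding 18 sub-areas over V1/V2/V3.

Sub-area numbering follows the convention: within each area, local sub-areas
1-3 are dorsal (lower visual field) and 4-6 are ventral (upper visual field),
each ordered from central to peripheral eccentricity.  Global indices 0-17
are ``area_index * 6 + local_index`` with areas ordered V1, V2, V3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import SurfaceMesh

__all__ = [
    "RetinotopicMap",
    "AreaLabels",
    "SubAreaParcellation",
    "compute_snr",
    "smooth_phase_map",
    "segment_subareas",
    "circular_mean_deg",
    "SNR_THRESHOLD",
    "SMOOTHING_ITERATIONS",
    "AREA_NAMES",
    "N_SUBAREAS",
    "subarea_name",
    "SUBAREA_NAMES",
]

#: Default reliability threshold on the stimulus-frequency SNR.
SNR_THRESHOLD = 5.0
#: Default number of neighbourhood-mean smoothing passes.
SMOOTHING_ITERATIONS = 4

AREA_NAMES = ("V1", "V2", "V3")
N_SUBAREAS = 18


def subarea_name(index: int) -> str:
    """Human-readable sub-area name, e.g. ``V1d1`` or ``V2v5``."""
    area, local = divmod(int(index), 6)
    hemi = "d" if local < 3 else "v"
    return f"{AREA_NAMES[area]}{hemi}{local + 1}"


SUBAREA_NAMES = tuple(subarea_name(i) for i in range(N_SUBAREAS))


@dataclass
class RetinotopicMap:
    """Per-vertex eccentricity (deg), polar angle (deg in [0, 360)) and SNR."""

    eccentricity: np.ndarray
    polar_angle: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.eccentricity = np.asarray(self.eccentricity, dtype=float)
        self.polar_angle = np.asarray(self.polar_angle, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        n = len(self.eccentricity)
        if len(self.polar_angle) != n or len(self.snr) != n:
            raise ValueError("eccentricity, polar_angle and snr must be congruent")
        if not np.all(np.isfinite(self.eccentricity)):
            raise ValueError("eccentricity must be finite")
        if np.any(self.eccentricity < 0):
            raise ValueError("eccentricity must be non-negative")
        if np.any(self.snr < 0):
            raise ValueError("snr must be non-negative")
        self.polar_angle = np.mod(self.polar_angle, 360.0)

    @property
    def n_vertices(self) -> int:
        return len(self.eccentricity)


@dataclass
class AreaLabels:
    """Disjoint vertex index sets for the visual areas V1, V2, V3."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray

    def __post_init__(self) -> None:
        self.v1 = np.unique(np.asarray(self.v1, dtype=np.int64))
        self.v2 = np.unique(np.asarray(self.v2, dtype=np.int64))
        self.v3 = np.unique(np.asarray(self.v3, dtype=np.int64))
        sets = [set(self.v1), set(self.v2), set(self.v3)]
        for i in range(3):
            if not sets[i]:
                raise ValueError(f"area {AREA_NAMES[i]} is empty")
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("area labels must be pairwise disjoint")

    @property
    def areas(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.v1, self.v2, self.v3)

    def union(self) -> np.ndarray:
        return np.concatenate(self.areas)

    def area_of_vertex(self, n_vertices: int) -> np.ndarray:
        """Per-vertex area index (0..2) or -1 outside the labels."""
        out = np.full(n_vertices, -1, dtype=np.int64)
        for a, idx in enumerate(self.areas):
            out[idx] = a
        return out


@dataclass
class SubAreaParcellation:
    """The 18 disjoint sub-area vertex sets over V1/V2/V3.

    ``sub_areas[i]`` is the vertex index array of global sub-area ``i``;
    ``area_of[i]``, ``hemifield_of[i]`` ('dorsal'/'ventral') and
    ``eccentricity_bin_of[i]`` (0..2, central to peripheral) describe it.
    ``eccentricity_cuts[area]`` holds the raw-degree bin edges used.
    """

    sub_areas: list
    eccentricity_cuts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sub_areas) != N_SUBAREAS:
            raise ValueError(f"expected {N_SUBAREAS} sub-area sets")
        self.sub_areas = [np.unique(np.asarray(s, dtype=np.int64)) for s in self.sub_areas]
        seen: set[int] = set()
        for s in self.sub_areas:
            vs = set(int(v) for v in s)
            if vs & seen:
                raise ValueError("sub-areas must be pairwise disjoint")
            seen |= vs

    @property
    def area_of(self) -> np.ndarray:
        return np.repeat(np.arange(3), 6)

    @property
    def hemifield_of(self) -> list:
        return ["dorsal" if (i % 6) < 3 else "ventral" for i in range(N_SUBAREAS)]

    @property
    def eccentricity_bin_of(self) -> np.ndarray:
        return np.array([i % 3 for i in range(N_SUBAREAS)])

    def vertex_subarea(self, n_vertices: int) -> np.ndarray:
        """Per-vertex global sub-area index (0..17) or -1 if unassigned."""
        out = np.full(n_vertices, -1, dtype=np.int64)
        for i, s in enumerate(self.sub_areas):
            out[s] = i
        return out

    def included_vertices(self) -> np.ndarray:
        return np.concatenate([s for s in self.sub_areas if len(s)]) if any(
            len(s) for s in self.sub_areas
        ) else np.empty(0, dtype=np.int64)


def compute_snr(
    timeseries: np.ndarray,
    stimulus_frequency_index: int,
    *,
    exclude_stimulus_bin: bool = True,
) -> np.ndarray:
    """Stimulus-frequency SNR of phase-encoded fMRI time-series.

    SNR is the magnitude of the discrete-Fourier spectrum at the stimulus
    frequency divided by the standard deviation of the magnitude spectrum.
    The DC bin is always excluded from the spectrum statistics;
    ``exclude_stimulus_bin`` (default) additionally leaves the stimulus bin
    out of the standard deviation so a strong response does not inflate its
    own noise estimate.

    Parameters
    ----------
    timeseries
        ``(T,)`` single series or ``(V, T)`` per-vertex series, T >= 8.
    stimulus_frequency_index
        Index of the stimulus frequency in the one-sided spectrum;
        must satisfy ``0 < index < T // 2``.

    Returns
    -------
    Scalar SNR for a 1-D input, else ``(V,)`` array.  Scale-invariant:
    ``compute_snr(c * x) == compute_snr(x)`` for any ``c > 0``.
    """
    x = np.asarray(timeseries, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[1]
    if n < 8:
        raise ValueError("time-series must have length >= 8")
    k = int(stimulus_frequency_index)
    if not 0 < k < n // 2:
        raise ValueError("stimulus frequency index must lie strictly between DC and Nyquist")
    spectrum = np.abs(np.fft.rfft(x, axis=1))
    signal = spectrum[:, k]
    noise_bins = spectrum[:, 1:]  # DC excluded
    if exclude_stimulus_bin:
        keep = np.ones(noise_bins.shape[1], dtype=bool)
        keep[k - 1] = False
        noise_bins = noise_bins[:, keep]
    sd = noise_bins.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("spectrum standard deviation is zero (constant series?)")
    snr = signal / sd
    return float(snr[0]) if one_d else snr


def circular_mean_deg(angles_deg: np.ndarray, axis=None) -> np.ndarray:
    """Circular mean of angles in degrees, result in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    s = np.sin(a).mean(axis=axis)
    c = np.cos(a).mean(axis=axis)
    out = np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)
    return np.where(out >= 360.0, 0.0, out)  # guard the -0.0 % 360 == 360 case


def smooth_phase_map(
    mesh: SurfaceMesh,
    phase: np.ndarray,
    snr: np.ndarray,
    snr_threshold: float = SNR_THRESHOLD,
    iterations: int = SMOOTHING_ITERATIONS,
    circular: bool = False,
) -> np.ndarray:
    """Iterated SNR-gated neighbourhood-mean smoothing of a phase map.

    Each iteration replaces every vertex value by the mean over its 1-ring
    neighbourhood (centre vertex included) restricted to vertices with
    ``snr >= snr_threshold``; vertices without any reliable vertex in their
    neighbourhood keep their current value.  Low-SNR vertices thus receive
    smoothed values from reliable neighbours but never contribute.  With
    ``circular=True`` the mean is the circular (unit-vector) mean, the right
    choice for polar angle which wraps at 360 deg.
    """
    phase = np.asarray(phase, dtype=float)
    snr = np.asarray(snr, dtype=float)
    if len(phase) != mesh.n_vertices or len(snr) != mesh.n_vertices:
        raise ValueError("phase and snr must have one value per mesh vertex")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    reliable = snr >= snr_threshold
    neighbors = mesh.neighbors

    # Precompute the reliable closed neighbourhood of every vertex.
    rings = []
    for v in range(mesh.n_vertices):
        ring = np.append(neighbors[v], v)
        rings.append(ring[reliable[ring]])

    out = phase.copy()
    for _ in range(int(iterations)):
        new = out.copy()
        for v, ring in enumerate(rings):
            if len(ring) == 0:
                continue
            if circular:
                a = np.deg2rad(out[ring])
                s, c = np.sin(a).mean(), np.cos(a).mean()
                if np.hypot(s, c) < 1e-12:
                    continue  # antipodal cancellation: keep current value
                val = np.mod(np.rad2deg(np.arctan2(s, c)), 360.0)
                new[v] = 0.0 if val >= 360.0 else val
            else:
                new[v] = out[ring].mean()
        out = new
    return out


def _split_eccentricity(ecc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalise eccentricity and cut at thirds.

    Returns (bin index 0..2 per entry, raw-degree cut edges length 4).
    Bins are lower-inclusive half-open, the last bin closed.
    """
    lo, hi = float(ecc.min()), float(ecc.max())
    span = hi - lo
    edges = np.array([lo, lo + span / 3.0, lo + 2.0 * span / 3.0, hi])
    if span == 0:
        return np.zeros(len(ecc), dtype=np.int64), edges
    norm = (ecc - lo) / span
    bins = np.minimum((norm * 3).astype(np.int64), 2)
    return bins, edges


def segment_subareas(
    mesh: SurfaceMesh,
    labels: AreaLabels,
    retinotopy: RetinotopicMap,
    snr_threshold: float = SNR_THRESHOLD,
    require_both_hemifields: bool = True,
) -> SubAreaParcellation:
    """Segment V1/V2/V3 into 18 sub-areas from smoothed retinotopy.

    Per area: vertices with ``snr >= snr_threshold`` are split into upper
    (polar angle strictly in (0, 180), ventral cortex) and lower (dorsal)
    hemifield sets -- boundary angles go to the dorsal set -- and each
    hemifield is cut into three eccentricity bins at 1/3 and 2/3 of the
    area-normalised eccentricity range (equally spaced in the visual field).
    Vertices failing the SNR gate are omitted from the parcellation.

    Raises
    ------
    ValueError
        If an area has fewer than 6 reliable vertices, or (by default) if a
        hemifield of an area is empty; pass ``require_both_hemifields=False``
        to accept empty hemifield segments instead.
    """
    if retinotopy.n_vertices != mesh.n_vertices:
        raise ValueError("retinotopy must be congruent with the mesh")
    sub_areas: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * N_SUBAREAS
    cuts: dict[str, list[float]] = {}
    for a, verts in enumerate(labels.areas):
        verts = verts[retinotopy.snr[verts] >= snr_threshold]
        if len(verts) < 6:
            raise ValueError(
                f"area {AREA_NAMES[a]} has {len(verts)} reliable vertices; need >= 6"
            )
        ang = retinotopy.polar_angle[verts]
        upper = (ang > 0) & (ang < 180)  # upper visual field -> ventral cortex
        ecc_bins, edges = _split_eccentricity(retinotopy.eccentricity[verts])
        cuts[AREA_NAMES[a]] = [float(e) for e in edges]
        for hemi_idx, mask in ((0, ~upper), (1, upper)):  # dorsal first
            if require_both_hemifields and not mask.any():
                which = "dorsal" if hemi_idx == 0 else "ventral"
                raise ValueError(f"area {AREA_NAMES[a]} has an empty {which} hemifield")
            for b in range(3):
                sel = verts[mask & (ecc_bins == b)]
                sub_areas[a * 6 + hemi_idx * 3 + b] = sel
    return SubAreaParcellation(sub_areas=sub_areas, eccentricity_cuts=cuts)
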