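"""18x18 connectivity, percent and closeness matrices and the retinotopic-order ratio.

Matrix rows/columns follow the fixed sub-area ordering V1d1..V1v6, V2d1..V2v6,
V3d1..V3v6 (indices 0-17).  All matrices are symmetric with zero diagonal:
diagonal elements would represent self connections of a sub-area with itself
and are excluded throughout.  Percent matrices normalise each unique
off-diagonal element by the total streamline count over all pairs, so the
upper-triangle sum is exactly 100.

For a 6x6 inter-area block (e.g. V1-V2), the diagonal holds the retinotopic
connections (same sub-area number in both areas) and the 30 off-diagonal
elements the non-retinotopic ones; the ratio of total retinotopic to
non-retinotopic percent connectivity indexes the retinotopic order.
"""

from __future__ import annotations

import numpy as np

from .retinotopy import N_SUBAREAS

__all__ = [
    "build_count_matrix",
    "percent_matrix",
    "closeness_matrix",
    "group_average",
    "inter_area_block",
    "retinotopic_ratio",
    "overall_retinotopic_ratio",
    "block_percent_contributions",
    "AREA_PAIRS",
]

#: Inter-area pairs in reporting order (area indices: 0=V1, 1=V2, 2=V3).
AREA_PAIRS = ((0, 1), (1, 2), (0, 2))


def _check_square(m: np.ndarray, n: int = N_SUBAREAS) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix, got {m.shape}")
    return m


def build_count_matrix(assignments: list, n: int = N_SUBAREAS) -> np.ndarray:
    """Symmetric streamline count matrix from accepted assignments.

    Element ``(i, j) == (j, i)`` counts accepted streamlines assigned the
    pair ``(i, j)``; the diagonal (self connections) is forced to zero.
    """
    counts = np.zeros((n, n), dtype=np.int64)
    for a in assignments:
        if not getattr(a, "accepted", False):
            continue
        i, j = a.subarea_pair
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"sub-area pair {a.subarea_pair} out of range")
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    np.fill_diagonal(counts, 0)
    return counts


def percent_matrix(counts: np.ndarray) -> np.ndarray:
    """Percent connectivity: each unique element scaled by 100 / total.

    The total is the sum over unique off-diagonal elements (self connections
    excluded), so the upper-triangle sum of the result is 100.
    """
    counts = _check_square(counts, n=len(np.asarray(counts)))
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    upper = np.triu(counts, k=1)
    total = upper.sum()
    if total == 0:
        raise ValueError("percent matrix undefined: no streamlines counted")
    out = counts * (100.0 / total)
    np.fill_diagonal(out, 0.0)
    return out


def closeness_matrix(assignments: list, n: int = N_SUBAREAS) -> np.ndarray:
    """Mean reciprocal streamline length (1/mm) per sub-area pair.

    Reciprocal length is a proxy for anatomical closeness of the connected
    patches.  Elements with no connecting streamline are NaN (flagged
    undefined rather than zero, since zero would mean "infinitely far").
    """
    sums = np.zeros((n, n))
    nums = np.zeros((n, n), dtype=np.int64)
    for a in assignments:
        if not getattr(a, "accepted", False):
            continue
        i, j = a.subarea_pair
        if i == j:
            continue
        if not np.isfinite(a.length_mm) or a.length_mm <= 0:
            raise ValueError("closeness requires positive streamline lengths")
        for r, c in ((i, j), (j, i)):
            sums[r, c] += 1.0 / a.length_mm
            nums[r, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(nums > 0, sums / np.maximum(nums, 1), np.nan)
    np.fill_diagonal(out, np.nan)
    return out


def group_average(matrices: list) -> np.ndarray:
    """Element-wise mean over per-hemisphere matrices."""
    if len(matrices) == 0:
        raise ValueError("need at least one matrix")
    mats = [np.asarray(m, dtype=float) for m in matrices]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("matrix shape mismatch in group average")
    return np.mean(mats, axis=0)


def inter_area_block(matrix: np.ndarray, area_a: int, area_b: int) -> np.ndarray:
    """The 6x6 block of an 18x18 matrix for an (ordered) area pair."""
    m = _check_square(matrix)
    a, b = sorted((int(area_a), int(area_b)))
    return m[6 * a : 6 * a + 6, 6 * b : 6 * b + 6]


def retinotopic_ratio(block: np.ndarray) -> tuple[float, float, float]:
    """Retinotopic %, non-retinotopic % and their ratio for a 6x6 block.

    The 6 diagonal elements are the retinotopic connections, the 30
    off-diagonal elements the non-retinotopic ones.  The ratio is
    ``+inf`` when the non-retinotopic sum is zero but the retinotopic sum is
    positive; an all-zero block is an error.
    """
    b = np.asarray(block, dtype=float)
    if b.shape != (6, 6):
        raise ValueError("expected a 6x6 inter-area block")
    if np.any(b < 0):
        raise ValueError("block must be non-negative")
    ret = float(np.trace(b))
    nonret = float(b.sum() - np.trace(b))
    if ret == 0 and nonret == 0:
        raise ValueError("retinotopic ratio undefined for an all-zero block")
    ratio = np.inf if nonret == 0 else ret / nonret
    return ret, nonret, ratio


def overall_retinotopic_ratio(matrix: np.ndarray) -> tuple[float, float, float]:
    """Retinotopic ratio pooled over the three inter-area blocks."""
    m = _check_square(matrix)
    ret = nonret = 0.0
    for a, b in AREA_PAIRS:
        blk = inter_area_block(m, a, b)
        ret += float(np.trace(blk))
        nonret += float(blk.sum() - np.trace(blk))
    if ret == 0 and nonret == 0:
        raise ValueError("retinotopic ratio undefined: no inter-area connectivity")
    ratio = np.inf if nonret == 0 else ret / nonret
    return ret, nonret, ratio


def block_percent_contributions(percent: np.ndarray) -> dict:
    """Percent mass per inter-area and intra-area block (sums to 100).

    Inter-area blocks contribute all 36 elements (each is a unique pair);
    intra-area blocks contribute their upper triangle only.
    """
    m = _check_square(percent)
    out = {}
    for a, b in AREA_PAIRS:
        out[f"V{a + 1}-V{b + 1}"] = float(inter_area_block(m, a, b).sum())
    for a in range(3):
        blk = m[6 * a : 6 * a + 6, 6 * a : 6 * a + 6]
        out[f"V{a + 1}-V{a + 1}"] = float(np.triu(blk, k=1).sum())
    return out
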