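"""Element-wise significance of streamline counts against null tractography.

The null hypothesis is that an observed count arises purely from tractography
artefacts (length bias, geometry) as captured by isotropic null-distribution
tractography.  Two tests are run per matrix element over hemispheres:

* Poisson sum test — each hemisphere's count is modelled as
  ``N_ij^h ~ Pois(mu_ij^h)`` with ``mu_ij^h`` the mean null count of that
  hemisphere; the sum over hemispheres is then Poisson with the summed mean,
  giving an exact one-tailed tail probability ``P(X >= S)``.
* Paired one-tailed t-test — on the per-hemisphere differences
  ``N_ij^h - mu_ij^h`` with alternative "mean difference > 0"; weaker
  distributional assumptions, and pairing absorbs hemisphere-level
  differences in tractography performance.

No multiple-testing correction is applied: each element is tested on its own
at the chosen alpha (default 0.05).  Sensitivity is the fraction of
retinotopic elements detected significant; specificity the fraction of
non-retinotopic elements correctly non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .retinotopy import N_SUBAREAS
from .connectivity import AREA_PAIRS

__all__ = [
    "ALPHA",
    "RetinotopyPattern",
    "block_pattern",
    "inter_area_pattern",
    "null_mean_matrix",
    "poisson_test",
    "paired_t_test",
    "significance_mask",
    "sensitivity_specificity",
]

#: Default significance level (95 % significance).
ALPHA = 0.05


@dataclass(frozen=True)
class RetinotopyPattern:
    """Which matrix elements count as retinotopic within an evaluation scope.

    ``retinotopic`` and ``scope`` are congruent boolean matrices; elements
    outside ``scope`` are ignored.  ``unique`` restricts counting to the
    upper triangle (used for symmetric full matrices so each pair is counted
    once; inter-area blocks have no such redundancy).
    """

    retinotopic: np.ndarray
    scope: np.ndarray
    unique: bool = False

    def __post_init__(self) -> None:
        if self.retinotopic.shape != self.scope.shape:
            raise ValueError("pattern masks must be congruent")


def block_pattern() -> RetinotopyPattern:
    """Pattern for one 6x6 inter-area block: diagonal retinotopic (6 vs 30)."""
    eye = np.eye(6, dtype=bool)
    return RetinotopyPattern(retinotopic=eye, scope=np.ones((6, 6), dtype=bool))


def inter_area_pattern() -> RetinotopyPattern:
    """Pattern over all inter-area elements of the 18x18 matrix."""
    ret = np.zeros((N_SUBAREAS, N_SUBAREAS), dtype=bool)
    scope = np.zeros((N_SUBAREAS, N_SUBAREAS), dtype=bool)
    for a, b in AREA_PAIRS:
        scope[6 * a : 6 * a + 6, 6 * b : 6 * b + 6] = True
        for k in range(6):
            ret[6 * a + k, 6 * b + k] = True
    return RetinotopyPattern(retinotopic=ret, scope=scope, unique=False)


def null_mean_matrix(null_counts: list) -> np.ndarray:
    """Per-hemisphere null mean: element-wise mean over the null repeats.

    The mean is kept as a (possibly non-integer) Poisson mean parameter.
    """
    if len(null_counts) == 0:
        raise ValueError("need at least one null count matrix")
    return np.mean([np.asarray(m, dtype=float) for m in null_counts], axis=0)


def _stack(counts: list, nulls: list) -> tuple[np.ndarray, np.ndarray]:
    c = np.stack([np.asarray(m, dtype=float) for m in counts])
    m = np.stack([np.asarray(x, dtype=float) for x in nulls])
    if c.shape != m.shape:
        raise ValueError("counts and null means must cover the same hemispheres")
    if np.any(c < 0) or np.any(m < 0):
        raise ValueError("counts and null means must be non-negative")
    return c, m


def poisson_test(counts: list, null_means: list) -> np.ndarray:
    """One-tailed Poisson sum test per matrix element.

    With ``S = sum_h N_ij^h`` and ``M = sum_h mu_ij^h``, returns
    ``p = P(X >= S)`` for ``X ~ Pois(M)`` (tail inclusive of the observed
    value).  For ``M == 0``: p is 1 when ``S == 0`` and 0 otherwise.
    """
    c, m = _stack(counts, null_means)
    S = c.sum(axis=0)
    M = m.sum(axis=0)
    p = np.ones_like(M, dtype=float)
    pos = M > 0
    p[pos] = stats.poisson.sf(S[pos] - 1, M[pos])
    zero = ~pos
    p[zero] = np.where(S[zero] == 0, 1.0, 0.0)
    return p


def paired_t_test(counts: list, null_means: list) -> np.ndarray:
    """Paired one-tailed t-test per element on ``N_ij^h - mu_ij^h``.

    Alternative: mean difference > 0.  Degenerate zero-variance elements are
    resolved by the limiting behaviour of the t statistic: p = 0 for a
    positive mean difference, p = 1 for a zero or negative one.
    """
    c, m = _stack(counts, null_means)
    if len(c) < 2:
        raise ValueError("paired t-test needs at least 2 hemispheres")
    d = c - m
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    p = np.empty_like(mean)
    degen = sd == 0
    p[degen] = np.where(mean[degen] > 0, 0.0, 1.0)
    ok = ~degen
    t = mean[ok] / (sd[ok] / np.sqrt(len(d)))
    p[ok] = stats.t.sf(t, df=len(d) - 1)
    return p


def significance_mask(p_values: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """Boolean mask of significant elements: ``p < alpha`` (no correction)."""
    return np.asarray(p_values, dtype=float) < alpha


def sensitivity_specificity(
    mask: np.ndarray, pattern: RetinotopyPattern
) -> tuple[float, float]:
    """Sensitivity and specificity of a significance mask for retinotopy.

    sensitivity = significant retinotopic elements / retinotopic elements;
    specificity = non-significant non-retinotopic / non-retinotopic elements.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pattern.scope.shape:
        raise ValueError("mask shape does not match the pattern scope")
    scope = pattern.scope.copy()
    if pattern.unique:
        scope &= np.triu(np.ones_like(scope), k=1).astype(bool)
    ret = scope & pattern.retinotopic
    nonret = scope & ~pattern.retinotopic
    if ret.sum() == 0 or nonret.sum() == 0:
        raise ValueError("pattern scope is degenerate")
    sensitivity = float(mask[ret].sum() / ret.sum())
    specificity = float((~mask[nonret]).sum() / nonret.sum())
    return sensitivity, specificity
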