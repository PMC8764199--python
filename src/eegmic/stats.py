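"""Inferential statistics for group comparison of EEG-derived measures.

Permutation-based two-sample t-test (Welch statistic), topographic analysis
of variance (TANOVA) on subject-level maps with polarity alignment,
Mann-Whitney U for ordinal scores, Spearman rank correlation, and
Shapiro-Wilk normality routing. Permutation p-values respect the
``(1 + count) / (n_perm + 1)`` floor, so the smallest reportable p is
``1/(n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult", "permutation_ttest", "tanova", "mann_whitney_u",
    "spearman_rho", "shapiro_wilk_normality",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    denom = np.sqrt(vx / nx + vy / ny)
    if denom == 0:
        raise ValueError("zero variance in both samples: t undefined")
    return float((y.mean() - x.mean()) / denom)


def _welch_t_permuted(pooled: np.ndarray, nx: int,
                      perm_idx: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over rows of permutation indices."""
    permuted = pooled[perm_idx]                     # n_perm x n
    gx, gy = permuted[:, :nx], permuted[:, nx:]
    vx = gx.var(axis=1, ddof=1)
    vy = gy.var(axis=1, ddof=1)
    denom = np.sqrt(vx / gx.shape[1] + vy / gy.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (gy.mean(axis=1) - gx.mean(axis=1)) / denom
    return np.where(denom > 0, t, 0.0)


def permutation_ttest(x, y, n_perm: int = 5000,
                      seed: int | np.random.Generator | None = None) -> TestResult:
    """Two-sided permutation test with the Welch t statistic.

    Group labels are permuted uniformly; p = (1 + #{|t*| >= |t|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = _welch_t(x, y)
    pooled = np.concatenate([x, y])
    n = pooled.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    t_perm = _welch_t_permuted(pooled, x.size, perm_idx)
    count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return TestResult("permutation_welch_t", t_obs, p, n_permutations=n_perm)


def _align_polarity(maps: np.ndarray) -> np.ndarray:
    """Flip each subject map's sign to agree with the pooled dominant axis.

    The axis is the leading eigenvector of the summed outer products of the
    unit-normalized maps, which is invariant to per-subject sign flips (and
    to group labels), so the aligned set — and hence the TANOVA statistic —
    does not depend on the arbitrary polarity of any input map.
    """
    unit = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    _vals, vecs = np.linalg.eigh(unit.T @ unit)
    axis = vecs[:, -1]
    signs = np.sign(unit @ axis)
    signs[signs == 0] = 1.0
    return unit * signs[:, None]


def _cosine_distance_between_means(aligned: np.ndarray, n1: int) -> float:
    m1 = aligned[:n1].mean(axis=0)
    m2 = aligned[n1:].mean(axis=0)
    d1, d2 = np.linalg.norm(m1), np.linalg.norm(m2)
    if d1 == 0 or d2 == 0:
        raise ValueError("zero-norm group mean map")
    return float(1.0 - abs(m1 @ m2 / (d1 * d2)))


def tanova(maps_g1: np.ndarray, maps_g2: np.ndarray, n_perm: int = 5000,
           seed: int | np.random.Generator | None = None) -> TestResult:
    """Topographic ANOVA: cosine spatial distance with label permutation.

    Subject maps are unit-normalized and polarity-aligned to the pooled
    grand mean (which is permutation-invariant), then the statistic
    ``1 - |cos|`` between the two group-mean maps is referenced to its
    permutation distribution over group-label shuffles.
    """
    maps_g1 = np.atleast_2d(np.asarray(maps_g1, dtype=float))
    maps_g2 = np.atleast_2d(np.asarray(maps_g2, dtype=float))
    if maps_g1.shape[1] != maps_g2.shape[1]:
        raise ValueError("groups must share the channel montage")
    if len(maps_g1) < 2 or len(maps_g2) < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = len(maps_g1)
    aligned = _align_polarity(np.vstack([maps_g1, maps_g2]))
    stat_obs = _cosine_distance_between_means(aligned, n1)

    n = len(aligned)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    g1 = aligned[perm_idx[:, :n1]]                  # n_perm x n1 x C
    g2 = aligned[perm_idx[:, n1:]]
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    norms = np.linalg.norm(m1, axis=1) * np.linalg.norm(m2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("pc,pc->p", m1, m2) / norms
    stat_perm = 1.0 - np.abs(np.where(norms > 0, cos, 0.0))
    count = int(np.sum(stat_perm >= stat_obs - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return TestResult("tanova_cosine", stat_obs, p, n_permutations=n_perm)


def mann_whitney_u(high, low) -> TestResult:
    """Mann-Whitney U of the high-risk sample against the low-risk sample.

    The statistic is U1 = #{high > low} + 0.5 * #{ties} over all cross
    pairs; the p-value comes from the standard two-sided test (exact when
    sample sizes permit, otherwise normal approximation with tie
    correction, as implemented by scipy).
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if high.size == 0 or low.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(high, low, alternative="two-sided", method="auto")
    return TestResult("mann_whitney_u1", float(res.statistic),
                      float(res.pvalue))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman_rho", float(rho), float(p))


def shapiro_wilk_normality(x) -> TestResult:
    """Shapiro-Wilk W; routes descriptive reporting (mean+-SD vs median/IQR)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.unique(x).size == 1:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return TestResult("shapiro_wilk_w", float(w), float(p))
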