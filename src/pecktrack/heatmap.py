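"""Spatial peck statistics: heatmaps, difference maps, concentration curves.

The registration region is sectioned into ``grid_n`` x ``grid_n`` equal
squares (15 x 15 by default; on the 5 x 5 cm region each square covers
(5/15)^2 ~ 0.11 cm^2). Pecks are counted per square, and — because total
peck counts differ between animals — expressed as relative percentages,

    relPecks = (100 / allPecks) * pecks per square.

Peck *concentration* is summarised by the cumulative curve: squares are
ranked by descending peck count and the cumulative share of pecks is
accumulated over ranks. A focused pecker reaches 1 within a few squares;
a dispersed pecker needs many. Correct- and error-trial concentration
profiles are compared with a two-sample Kolmogorov-Smirnov statistic on
these ranked curves, at a Bonferroni-adjusted alpha (0.05/8 = 0.00625
for an eight-subject study).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import distributions

from pecktrack.data import DisplayGeometry, PeckPool

DEFAULT_ALPHA_ADJUSTED = 0.05 / 8  # Bonferroni over eight subjects


@dataclass(frozen=True)
class HeatmapGrid:
    """Relative peck percentages per square; entries sum to 100 (or the
    grid is all-zero when it holds no pecks).

    ``values[ix, iy]`` covers x in [ix*d, (ix+1)*d), y in [iy*d, (iy+1)*d)
    with d the square side; the top/right region edge folds into the last
    square so every in-bounds peck lands in exactly one cell.
    """

    values: np.ndarray
    total_pecks: int
    geometry: DisplayGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.geometry.grid_n, self.geometry.grid_n):
            raise ValueError("heatmap shape does not match geometry")
        if (v < 0).any():
            raise ValueError("heatmap values must be non-negative")
        if self.total_pecks > 0 and abs(v.sum() - 100.0) > 1e-9:
            raise ValueError("heatmap must sum to 100")


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative share of pecks over squares ranked by descending count."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (np.diff(f) < -1e-12).any():
            raise ValueError("cumulative curve must be nondecreasing")


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison of two ranked cumulative peck curves."""

    D: float
    p: float
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_adjusted


def bin_pecks(pool: PeckPool, geometry: DisplayGeometry | None = None) -> np.ndarray:
    """Count pool pecks per grid square.

    Returns an integer (grid_n, grid_n) array indexed ``[ix, iy]`` with
    ix = floor(x / d), iy = floor(y / d); coordinates exactly on the
    top/right region edge map to the last index. The grid total equals
    the pool size.
    """
    geometry = geometry or DisplayGeometry()
    n = geometry.grid_n
    d = geometry.square_side
    counts = np.zeros((n, n), dtype=int)
    if len(pool) == 0:
        return counts
    xy = pool.xy
    ix = np.minimum((xy[:, 0] // d).astype(int), n - 1)
    iy = np.minimum((xy[:, 1] // d).astype(int), n - 1)
    np.add.at(counts, (ix, iy), 1)
    return counts


def relative_heatmap(
    counts: np.ndarray, geometry: DisplayGeometry | None = None
) -> HeatmapGrid:
    """Convert a count grid to relative percentages (relPecks)."""
    geometry = geometry or DisplayGeometry()
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if total == 0:
        warnings.warn("empty pool: returning an all-zero heatmap", stacklevel=2)
        values = np.zeros_like(counts, dtype=float)
    else:
        values = 100.0 * counts / total
    return HeatmapGrid(values=values, total_pecks=total, geometry=geometry)


def difference_map(a: HeatmapGrid, b: HeatmapGrid) -> np.ndarray:
    """Elementwise difference a - b of two relative heatmaps.

    Entries lie in [-100, 100] and sum to zero when both grids hold pecks.
    """
    if a.geometry != b.geometry:
        raise ValueError("heatmaps have different geometries")
    return np.asarray(a.values, dtype=float) - np.asarray(b.values, dtype=float)


def cumulative_curve(counts: np.ndarray) -> CumulativeCurve:
    """Cumulative peck share over squares ranked by descending count.

    Ranks squares from most- to least-pecked (ties broken by row-major
    cell index, which leaves the curve values unchanged) and accumulates
    the share of total pecks. The curve has grid_n^2 entries and ends at 1.
    """
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cumulative_curve requires at least one peck")
    flat = counts.ravel(order="C")
    # stable sort on negated counts = descending with row-major tie-break
    order = np.argsort(-flat, kind="stable")
    fractions = np.cumsum(flat[order]) / total
    return CumulativeCurve(fractions=fractions)


def compare_correct_error(
    pool_correct: PeckPool,
    pool_error: PeckPool,
    geometry: DisplayGeometry | None = None,
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED,
) -> KSResult:
    """KS comparison of correct- vs error-trial peck concentration.

    Each pool is binned and ranked by its own descending square order;
    D is the maximum absolute difference between the two cumulative
    curves over ranks. The p-value uses the asymptotic two-sample KS
    distribution with both sample sizes equal to the number of squares
    (grid_n^2). Note this measures a difference in *concentration*
    profiles, not in spatial location: the ranked curve is invariant to
    where on the display the squares sit.
    """
    geometry = geometry or DisplayGeometry()
    if len(pool_correct) == 0 or len(pool_error) == 0:
        raise ValueError("both pools must be non-empty")
    c1 = cumulative_curve(bin_pecks(pool_correct, geometry)).fractions
    c2 = cumulative_curve(bin_pecks(pool_error, geometry)).fractions
    D = float(np.max(np.abs(c1 - c2)))
    n = m = geometry.grid_n**2
    return KSResult(
        D=D, p=ks_two_sample_pvalue(D, n, m), alpha_adjusted=alpha_adjusted
    )


def ks_two_sample_pvalue(D: float, n: int, m: int) -> float:
    """Asymptotic two-sided two-sample KS p-value (Smirnov's formula with
    the effective sample size n*m/(n+m), as used by standard software)."""
    en = n * m / (n + m)
    return float(np.clip(distributions.kstwo.sf(D, int(round(en))), 0.0, 1.0))
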