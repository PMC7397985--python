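"""Posterior summaries: density-based modes, HPD regions, and
null-distribution comparisons.

Heritability posteriors from weakly informed animal models pile up against
zero and are strongly right-skewed, so the point estimate of choice is the
density mode (with a narrow kernel to resolve the peak) and the interval of
choice is the highest-posterior-density region, which for such shapes is
shorter than the equal-tail interval and may touch the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PosteriorSummary",
    "posterior_mode",
    "hpd_region",
    "summarize",
    "compare_to_null",
]

GRID_SIZE = 512


@dataclass
class PosteriorSummary:
    mode: float
    hpd_95: list[tuple[float, float]]
    mean: float
    median: float

    def hpd_low(self) -> float:
        return self.hpd_95[0][0]

    def hpd_high(self) -> float:
        return self.hpd_95[-1][1]


def posterior_mode(samples, bandwidth_adjust: float = 0.1) -> float:
    """Density-based mode: Gaussian KDE with Silverman bandwidth scaled by
    ``bandwidth_adjust`` (default 0.1 to resolve sharp peaks near zero),
    evaluated on a 512-point grid over the sample range; ties break toward
    the smaller value."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    kde.set_bandwidth(kde.factor * bandwidth_adjust)
    grid = np.linspace(lo, hi, GRID_SIZE)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])  # argmax returns the first (smallest)


def hpd_region(
    samples, probability: float = 0.95, allow_multimodal: bool = False,
) -> list[tuple[float, float]]:
    """Highest-posterior-density region of a posterior sample.

    Default (unimodal) path: the shortest interval containing
    ceil(probability * n) sorted samples.  Multimodal path: a KDE level set
    thresholded to enclose the requested mass, possibly several disjoint
    intervals.
    """
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples")
    if not allow_multimodal:
        k = math.ceil(probability * n)
        widths = x[k - 1:] - x[: n - k + 1]
        i = int(np.argmin(widths))
        return [(float(x[i]), float(x[i + k - 1]))]
    # KDE level set
    if x[0] == x[-1]:
        return [(float(x[0]), float(x[-1]))]
    kde = stats.gaussian_kde(x, bw_method="silverman")
    pad = 3.0 * kde.factor * x.std()
    grid = np.linspace(x[0] - pad, x[-1] + pad, 4 * GRID_SIZE)
    dens = kde(grid)
    dens = dens / dens.sum()
    order = np.argsort(dens)[::-1]
    mass = np.cumsum(dens[order])
    cutoff = dens[order[np.searchsorted(mass, probability)]]
    inside = dens >= cutoff
    intervals: list[tuple[float, float]] = []
    start = None
    for g, flag in zip(grid, inside):
        if flag and start is None:
            start = g
        elif not flag and start is not None:
            intervals.append((float(start), float(prev)))
            start = None
        prev = g
    if start is not None:
        intervals.append((float(start), float(grid[-1])))
    return intervals


def summarize(
    samples, bandwidth_adjust: float = 0.1, probability: float = 0.95,
    allow_multimodal: bool = False,
) -> PosteriorSummary:
    x = np.asarray(samples, dtype=float)
    return PosteriorSummary(
        mode=posterior_mode(x, bandwidth_adjust=bandwidth_adjust),
        hpd_95=hpd_region(x, probability=probability,
                          allow_multimodal=allow_multimodal),
        mean=float(x.mean()),
        median=float(np.median(x)),
    )


def compare_to_null(h2_samples, null_h2_samples) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of a posterior sample
    against the zero-heritability control posterior.

    Returns (U statistic for the first sample, two-sided p-value) using the
    normal approximation with tie correction.
    """
    a = np.asarray(h2_samples, dtype=float)
    b = np.asarray(null_h2_samples, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
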