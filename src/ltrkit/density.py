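"""Kernel-density estimation with mode reporting.

Shared by the insertion-age and Ks distribution stages: a Gaussian KDE
with Silverman bandwidth evaluated on a regular grid; modes are the local
maxima exceeding 10% of the global maximum, reported in ascending order.
Degenerate samples (fewer than five values, or zero spread) fall back to
a histogram / point mass, with a log notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

MODE_PROMINENCE = 0.10  # modes must exceed this fraction of the peak density


@dataclass
class DensityResult:
    grid: np.ndarray
    density: np.ndarray
    modes: list[float]
    bandwidth: float
    method: str  # "kde" | "histogram" | "point"


def _local_maxima(grid: np.ndarray, density: np.ndarray) -> list[float]:
    peak = float(density.max())
    if peak <= 0:
        return []
    modes = []
    for i in range(len(density)):
        left = density[i - 1] if i > 0 else -np.inf
        right = density[i + 1] if i < len(density) - 1 else -np.inf
        if density[i] > left and density[i] >= right and density[i] > MODE_PROMINENCE * peak:
            modes.append(float(grid[i]))
    return sorted(modes)


def density_modes(
    values,
    grid_points: int = 512,
    lower_bound: float | None = None,
) -> DensityResult:
    """Gaussian-KDE density (Silverman bandwidth) and its modes."""
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if x.size == 0:
        raise ValueError("no finite values")
    if np.ptp(x) == 0.0:
        return DensityResult(
            grid=np.array([x[0]]), density=np.array([1.0]),
            modes=[float(x[0])], bandwidth=0.0, method="point",
        )
    if x.size < 5:
        logger.info("fewer than 5 values: histogram fallback")
        counts, edges = np.histogram(x, bins="auto")
        centers = 0.5 * (edges[:-1] + edges[1:])
        return DensityResult(
            grid=centers, density=counts.astype(float),
            modes=_local_maxima(centers, counts.astype(float)),
            bandwidth=float(edges[1] - edges[0]), method="histogram",
        )
    kde = gaussian_kde(x, bw_method="silverman")
    bw = float(kde.factor * x.std(ddof=1))
    lo = x.min() - 3 * bw
    hi = x.max() + 3 * bw
    if lower_bound is not None:
        lo = max(lo, lower_bound)
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)
    return DensityResult(grid=grid, density=density,
                         modes=_local_maxima(grid, density),
                         bandwidth=bw, method="kde")
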