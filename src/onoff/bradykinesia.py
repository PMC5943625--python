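"""Per-period gait classification with an unsupervised patient threshold.

Stride fluidities are averaged over non-overlapping 10-min periods and
compared with a patient-specific threshold derived, without diaries, from
the distribution of that patient's own fluidity values:

* if the smoothed distribution shows two separated bell-shaped modes,
  each holding at least 15% of the data, the threshold is the midpoint of
  the two mode locations (``bimodal-midpoint``);
* otherwise it is the fluidity value left of the global mode where the
  density falls to 60% of the mode's density (``submode-shoulder``); for
  a Gaussian this sits at mode - 1.01 sigma.

The distribution is realised as a Gaussian KDE with Silverman bandwidth;
mode basins are delimited by density minima.  Low fluidity means
bradykinetic (Off-state) gait; means within +-1.7 m/s^2 of the threshold
are an intermediate zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .config import PipelineConfig
from .stride import StrideFeature

INDETERMINATE = "indeterminate"
BRADYKINETIC = "bradykinetic"
INTERMEDIATE = "intermediate"
NORMAL = "normal"


@dataclass(frozen=True)
class GaitPeriodStatus:
    period_index: int
    mean_fluidity: float | None
    status: str


@dataclass(frozen=True)
class PatientThreshold:
    theta: float  # m/s^2
    method: str  # 'bimodal-midpoint' | 'submode-shoulder'
    n_values: int


class TooFewStrides(ValueError):
    """Not enough fluidity values to estimate a threshold."""


def period_mean_fluidity(strides: list[StrideFeature]) -> dict[int, float]:
    """Arithmetic mean fluidity per 10-min period (absent key = no strides)."""
    sums: dict[int, list[float]] = {}
    for st in strides:
        sums.setdefault(st.period_index, []).append(st.fluidity)
    return {p: float(np.mean(v)) for p, v in sums.items()}


def _kde_grid(values: np.ndarray, n_grid: int = 512):
    kde = gaussian_kde(values, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, n_grid)
    return grid, kde(grid)


def estimate_threshold(
    values: np.ndarray | list[float], config: PipelineConfig | None = None
) -> PatientThreshold:
    """Unsupervised patient threshold from all of a patient's fluidities."""
    config = config or PipelineConfig()
    values = np.asarray(values, dtype=float)
    if values.size < config.min_strides_for_threshold:
        raise TooFewStrides(
            f"need >= {config.min_strides_for_threshold} fluidity values, got {values.size}"
        )
    grid, dens = _kde_grid(values)

    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1  # local maxima
    if interior.size >= 2:
        # basin boundaries at the density minima between consecutive modes
        edges = [grid[0]]
        for a, b in zip(interior[:-1], interior[1:]):
            edges.append(grid[a + int(np.argmin(dens[a:b]))])
        edges.append(grid[-1])
        masses = [
            np.mean((values >= lo) & (values < hi))
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        qualified = [
            (dens[m], grid[m]) for m, mass in zip(interior, masses)
            if mass >= config.bimodal_min_mass
        ]
        if len(qualified) >= 2:
            top2 = sorted(qualified, reverse=True)[:2]
            theta = float(np.mean([loc for _, loc in top2]))
            theta = float(np.clip(theta, values.min(), values.max()))
            return PatientThreshold(theta, "bimodal-midpoint", values.size)

    # submode shoulder: walk left from the global mode to the 60% crossing
    m = int(np.argmax(dens))
    target = config.shoulder_density_ratio * dens[m]
    i = m
    while i > 0 and dens[i - 1] >= target:
        i -= 1
    if i == 0:
        theta = grid[0]
    else:
        # linear interpolation of the crossing between grid[i-1] and grid[i]
        d0, d1 = dens[i - 1], dens[i]
        frac = (target - d0) / (d1 - d0) if d1 != d0 else 0.0
        theta = grid[i - 1] + frac * (grid[i] - grid[i - 1])
    theta = float(np.clip(theta, values.min(), values.max()))
    return PatientThreshold(theta, "submode-shoulder", values.size)


def classify_gait(
    period_index: int,
    mean_fluidity: float | None,
    threshold: PatientThreshold,
    config: PipelineConfig | None = None,
) -> GaitPeriodStatus:
    """Classify one period's gait against the patient threshold.

    Low mean fluidity => bradykinetic (config ``bradykinesia_low_fluidity``
    documents the direction); within +-1.7 m/s^2 of the threshold =>
    intermediate; no strides => indeterminate.
    """
    config = config or PipelineConfig()
    if mean_fluidity is None:
        return GaitPeriodStatus(period_index, None, INDETERMINATE)
    hw = config.intermediate_halfwidth
    d = mean_fluidity - threshold.theta
    if abs(d) <= hw:
        status = INTERMEDIATE
    elif (d < 0) == config.bradykinesia_low_fluidity:
        status = BRADYKINETIC
    else:
        status = NORMAL
    return GaitPeriodStatus(period_index, float(mean_fluidity), status)
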