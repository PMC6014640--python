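"""Automatic per-window choice of the classification feature.

The distribution of max-min amplitudes over a window decides which feature
the clustering stage gets. The range ``[0, MA]`` (MA = maximum amplitude in
the window) is split into 50 equal bins, the histogram is normalized by the
number of points and smoothed with a short centered moving average, and its
local extrema are read off. Scanning up from zero, the first local minimum
separates the near-zero noise mode from the physiologic modes; the local
maxima above it ("post-min maxima") identify the fetal and maternal
amplitude zones:

* exactly two post-min maxima separated by at least 35% of MA
  (``dmax_max >= 0.35 MA``) — amplitudes alone separate fetal from
  maternal RS-peaks; classify on **amplitude** (case 1, Scenario 1);
* exactly two post-min maxima closer than 35% of MA — amplitudes overlap;
  classify on **amplitude x RS-width in samples** (case 2, Scenario 2);
* a single post-min maximum — fetal and maternal amplitudes share one
  zone; classify on the **product** as well (case 3, Scenario 2);
* anything else (zero or more than two maxima) — fall back to amplitude.

All comparisons are relative to MA, so the decision is invariant to signal
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maxmin_features import MaxMinPoint

N_BINS = 50
SMOOTH_WIDTH = 5
DMAX_FRAC = 0.35
PROMINENCE_FLOOR = 0.005


@dataclass(frozen=True)
class DistributionSummary:
    """Smoothed normalized amplitude histogram of a window with its extrema."""

    MA: float
    bin_edges: np.ndarray = field(repr=False)
    raw_counts: np.ndarray = field(repr=False)
    normalized: np.ndarray = field(repr=False)
    smoothed: np.ndarray = field(repr=False)
    maxima_bins: np.ndarray = field(repr=False)
    minima_bins: np.ndarray = field(repr=False)
    first_min_bin: int | None
    post_min_maxima: np.ndarray = field(repr=False)
    dmax_max: float | None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class FeatureChoice:
    """The selected feature for one window, with the distribution evidence."""

    case_id: str  # case1 | case2 | case3 | fallback
    scenario: str  # scenario1 | scenario2
    feature_name: str  # amplitude | product
    feature_values: np.ndarray = field(repr=False)
    summary: DistributionSummary = field(repr=False)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    kernel = np.ones(width)
    return np.convolve(x, kernel, mode="same") / np.convolve(np.ones_like(x), kernel, mode="same")


def _series_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima/minima of a short series, plateau located at its first
    bin; boundary bins may be extrema via one-sided comparison."""
    n = y.size
    maxima, minima = [], []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left = y[i - 1] if i > 0 else None
        right = y[j + 1] if j + 1 < n else None
        is_max = (left is None or y[i] > left) and (right is None or y[i] > right)
        is_min = (left is None or y[i] < left) and (right is None or y[i] < right)
        # a flat whole series is neither
        if left is None and right is None:
            is_max = is_min = False
        if is_max:
            maxima.append(i)
        if is_min:
            minima.append(i)
        i = j + 1
    return np.array(maxima, dtype=np.int64), np.array(minima, dtype=np.int64)


def amplitude_distribution(
    points: list[MaxMinPoint],
    n_bins: int = N_BINS,
    smooth_width: int = SMOOTH_WIDTH,
    prominence_floor: float = PROMINENCE_FLOOR,
) -> DistributionSummary:
    """Build the smoothed normalized amplitude histogram of a window.

    Requires at least 2 points. The top bin edge is inclusive, so every
    amplitude (including MA itself) is counted and the normalized counts
    sum to one.
    """
    if len(points) < 2:
        raise ValueError("window too sparse: need at least 2 max-min points")
    amplitudes = np.array([p.amplitude for p in points])
    ma = float(amplitudes.max())
    edges = np.linspace(0.0, ma, n_bins + 1)
    counts, _ = np.histogram(amplitudes, bins=edges)
    normalized = counts / len(points)
    smoothed = _moving_average(normalized, smooth_width)

    maxima, minima = _series_extrema(smoothed)
    first_min = int(minima[0]) if minima.size else None
    if first_min is not None:
        post = maxima[maxima > first_min]
        post = post[smoothed[post] >= prominence_floor]  # ignore noise wiggles
    else:
        post = np.empty(0, dtype=np.int64)

    dmax = None
    if post.size >= 2:
        centers = 0.5 * (edges[:-1] + edges[1:])
        top2 = post[np.argsort(smoothed[post], kind="stable")[::-1][:2]]
        dmax = float(abs(centers[top2[0]] - centers[top2[1]]))

    return DistributionSummary(
        MA=ma,
        bin_edges=edges,
        raw_counts=counts,
        normalized=normalized,
        smoothed=smoothed,
        maxima_bins=maxima,
        minima_bins=minima,
        first_min_bin=first_min,
        post_min_maxima=post,
        dmax_max=dmax,
    )


def select_feature(
    points: list[MaxMinPoint],
    n_bins: int = N_BINS,
    smooth_width: int = SMOOTH_WIDTH,
    dmax_frac: float = DMAX_FRAC,
    prominence_floor: float = PROMINENCE_FLOOR,
) -> FeatureChoice:
    """Apply the case table to a window's amplitude distribution.

    A tie at exactly ``dmax_frac * MA`` counts as Scenario 1.
    ``feature_values`` is order-aligned with ``points``.
    """
    summary = amplitude_distribution(points, n_bins, smooth_width, prominence_floor)
    n_post = int(summary.post_min_maxima.size)
    if n_post == 2:
        if summary.dmax_max >= dmax_frac * summary.MA:
            case_id, scenario, feature = "case1", "scenario1", "amplitude"
        else:
            case_id, scenario, feature = "case2", "scenario2", "product"
    elif n_post == 1:
        case_id, scenario, feature = "case3", "scenario2", "product"
    else:
        case_id, scenario, feature = "fallback", "scenario1", "amplitude"

    if feature == "amplitude":
        values = np.array([p.amplitude for p in points])
    else:
        values = np.array([p.product for p in points])
    return FeatureChoice(
        case_id=case_id,
        scenario=scenario,
        feature_name=feature,
        feature_values=values,
        summary=summary,
    )


__all__ = [
    "DistributionSummary",
    "FeatureChoice",
    "amplitude_distribution",
    "select_feature",
]
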