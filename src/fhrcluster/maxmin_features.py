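"""Max-min point extraction: the RS-peak signature of a QRS complex.

An RS-peak candidate is a local maximum (R candidate) followed immediately
by a local minimum (S candidate). Two features are computed per point: the
amplitude distance ``max - min`` and the RS span in samples; their product
serves as the alternative classification feature when fetal and maternal
amplitudes are similar.

Plateaus (runs of equal samples bounded by strictly smaller/larger
neighbours, common in 16-bit quantized signals) count as one extremum
located at the run's first sample. A local maximum whose next extremum is
not a minimum is discarded: only the immediate max-to-min geometry is of
interest. No amplitude or time gating happens here — separating noise from
fetal and maternal RS-peaks is the clustering stage's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import EcgRecord


@dataclass(frozen=True)
class MaxMinPoint:
    """One local-max-followed-by-local-min event."""

    max_idx: int
    min_idx: int
    max_val: float
    min_val: float

    @property
    def amplitude(self) -> float:
        """Amplitude distance max - min (a.u.), strictly positive."""
        return self.max_val - self.min_val

    @property
    def n_samples(self) -> int:
        """RS span min_idx - max_idx in samples, >= 1."""
        return self.min_idx - self.max_idx

    @property
    def product(self) -> float:
        """amplitude * n_samples (a.u. * samples)."""
        return self.amplitude * self.n_samples


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima with plateau handling.

    Runs of equal values are compressed to their first sample; a run is an
    extremum when both flanking values are strictly smaller (max) or
    strictly larger (min). Signal boundaries are never extrema.
    """
    keep = np.empty(x.size, dtype=bool)
    keep[0] = True
    np.not_equal(x[1:], x[:-1], out=keep[1:])
    pos = np.flatnonzero(keep)  # first sample of each run
    xc = x[pos]
    if xc.size < 3:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rising = xc[1:-1] > xc[:-2]
    falling = xc[1:-1] > xc[2:]
    maxima = pos[1:-1][rising & falling]
    minima = pos[1:-1][(~rising) & (~falling)]
    return maxima, minima


def find_maxmin_points(record: EcgRecord | np.ndarray) -> list[MaxMinPoint]:
    """Locate every local maximum followed by a local minimum.

    Returns points ordered by ``max_idx``; each local max is used at most
    once, paired with the first later extremum only if that extremum is a
    local minimum. May return an empty list (e.g. monotone input).
    """
    x = record.samples if isinstance(record, EcgRecord) else np.asarray(record, dtype=float)
    if x.size < 3:
        return []
    maxima, minima = _extrema(x)
    if maxima.size == 0 or minima.size == 0:
        return []
    # the next extremum after each max; it is a min iff no other max intervenes
    nxt = np.searchsorted(minima, maxima, side="right")
    valid = nxt < minima.size
    cand_min = minima[np.clip(nxt, 0, minima.size - 1)]
    # discard a max whose following extremum is another max
    nxt_max = np.searchsorted(maxima, maxima, side="right")
    has_next_max = nxt_max < maxima.size
    next_max_pos = maxima[np.clip(nxt_max, 0, maxima.size - 1)]
    valid &= ~(has_next_max & (next_max_pos < cand_min))
    return [
        MaxMinPoint(int(mx), int(mn), float(x[mx]), float(x[mn]))
        for mx, mn in zip(maxima[valid], cand_min[valid])
    ]


def points_to_arrays(points: list[MaxMinPoint]) -> dict[str, np.ndarray]:
    """Column view of a point list (for vectorized feature work and debug dumps)."""
    return {
        "max_idx": np.array([p.max_idx for p in points], dtype=np.int64),
        "min_idx": np.array([p.min_idx for p in points], dtype=np.int64),
        "amplitude": np.array([p.amplitude for p in points]),
        "n_samples": np.array([p.n_samples for p in points], dtype=np.int64),
        "product": np.array([p.product for p in points]),
    }


__all__ = ["MaxMinPoint", "find_maxmin_points", "points_to_arrays"]
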