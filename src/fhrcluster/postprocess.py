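"""Fetal-cluster refinement and RR-based false-positive/negative correction.

Two stages turn the fetal-labelled max-min points into the final fetal
R-peak train:

**Refinement** re-checks every fetal-labelled point against limits derived
from the window's smoothed amplitude distribution: amplitudes must lie
above the noise/fetal boundary (the first local minimum of the
distribution) and below the fetal/maternal midpoint (when two post-noise
modes exist), and the RS span must not exceed a physiologic fetal QRS
width.

**Correction** scans the candidate RR series against a running median:
an implausibly short interval (or one implying a rate above the
physiologic fetal band) marks a false positive, and the pair member with
the smaller RS amplitude is dropped; an implausibly long interval (or one
implying a rate below the band) marks a false negative, and the gap is
searched at the expected beat position for the largest unused max-min
point to re-insert. The FP pass runs before the FN pass, each as a single
forward sweep, and every removal/insertion is recorded in an audit list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import ROLE_FETAL, ClusterResult
from .feature_select import DistributionSummary
from .maxmin_features import MaxMinPoint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefineConfig:
    """Limits for the classification-improvement stage.

    ``amp_low`` / ``amp_high`` override the distribution-derived bounds
    with absolute values when set. ``rs_width_max_ms`` caps the fetal RS
    span; ``maternal_refractory_ms`` (off by default) suppresses fetal
    candidates within a half-window of detected maternal peaks.
    """

    rs_width_max_ms: float = 60.0
    maternal_refractory_ms: float = 0.0
    amp_low: float | None = None
    amp_high: float | None = None

    def __post_init__(self) -> None:
        if self.rs_width_max_ms < 0 or self.maternal_refractory_ms < 0:
            raise ValueError("ms parameters must be >= 0")


@dataclass(frozen=True)
class CorrectionConfig:
    """RR-plausibility gates for the FP/FN correction stage.

    Intervals shorter than ``short_rr_frac`` (or longer than
    ``long_rr_frac``) times the running-median RR, or implying a rate
    outside ``[fhr_min_bpm, fhr_max_bpm]``, are treated as FP/FN evidence.
    """

    fhr_min_bpm: float = 100.0
    fhr_max_bpm: float = 220.0
    short_rr_frac: float = 0.5
    long_rr_frac: float = 1.5
    median_window_beats: int = 9
    search_margin_ms: float = 30.0

    def __post_init__(self) -> None:
        if not self.fhr_min_bpm < self.fhr_max_bpm:
            raise ValueError("fhr_min_bpm must be < fhr_max_bpm")
        if not 0 < self.short_rr_frac < 1 < self.long_rr_frac:
            raise ValueError("need 0 < short_rr_frac < 1 < long_rr_frac")


def _derive_amplitude_limits(
    summary: DistributionSummary, config: RefineConfig
) -> tuple[float, float]:
    """A_low = amplitude of the first local-minimum bin (noise boundary);
    A_high = midpoint of the two post-noise mode centers when both exist,
    else MA."""
    centers = summary.bin_centers
    if config.amp_low is not None:
        a_low = config.amp_low
    elif summary.first_min_bin is not None:
        a_low = float(centers[summary.first_min_bin])
    else:
        a_low = 0.0
    if config.amp_high is not None:
        a_high = config.amp_high
    elif summary.post_min_maxima.size >= 2:
        top2 = summary.post_min_maxima[
            np.argsort(summary.smoothed[summary.post_min_maxima], kind="stable")[::-1][:2]
        ]
        a_high = float(centers[top2].mean())
    else:
        a_high = summary.MA
    return a_low, a_high


def refine_fetal_cluster(
    points: list[MaxMinPoint],
    result: ClusterResult,
    summary: DistributionSummary,
    config: RefineConfig = RefineConfig(),
    fs: float = 1000.0,
    maternal_peaks: np.ndarray | None = None,
) -> list[MaxMinPoint]:
    """Keep fetal-role points that satisfy the amplitude and width limits.

    Returns the surviving candidates ordered by ``max_idx``; may be empty.
    """
    if result.roles is None:
        raise ValueError("cluster roles must be assigned before refinement")
    fetal_cluster = result.cluster_of(ROLE_FETAL)
    a_low, a_high = _derive_amplitude_limits(summary, config)
    max_span = config.rs_width_max_ms * fs / 1000.0
    kept = [
        p
        for p, lab in zip(points, result.labels)
        if lab == fetal_cluster and a_low <= p.amplitude <= a_high and p.n_samples <= max_span
    ]
    if config.maternal_refractory_ms > 0 and maternal_peaks is not None and len(maternal_peaks):
        half = config.maternal_refractory_ms * fs / 1000.0
        mp = np.asarray(maternal_peaks)
        kept = [p for p in kept if np.min(np.abs(mp - p.max_idx)) > half]
    return sorted(kept, key=lambda p: p.max_idx)


def _running_median(rr: np.ndarray, window: int) -> np.ndarray:
    """Centered running median over the RR series, window shrunk at the ends."""
    half = window // 2
    return np.array(
        [np.median(rr[max(0, i - half) : min(rr.size, i + half + 1)]) for i in range(rr.size)]
    )


def correct_fp_fn(
    candidates: np.ndarray,
    fs: float,
    config: CorrectionConfig = CorrectionConfig(),
    points: list[MaxMinPoint] | None = None,
    audit: list[dict] | None = None,
) -> np.ndarray:
    """RR-plausibility correction of a fetal R-peak candidate train.

    Parameters
    ----------
    candidates : array of int
        Strictly increasing R-peak sample indices.
    fs : float
        Sampling rate in Hz.
    points : list of MaxMinPoint, optional
        All max-min points of the record. Used to look up candidate
        amplitudes for the FP rule and to search gaps for missed beats in
        the FN rule; without them the FP rule removes the later beat of an
        implausible pair and the FN rule cannot insert.
    audit : list, optional
        Appended with one dict per removal/insertion (reason and indices).

    Fewer than 2 candidates pass through unchanged.
    """
    cand = np.asarray(candidates, dtype=np.int64)
    if cand.size < 2:
        return cand.copy()
    if audit is None:
        audit = []

    amp_by_idx: dict[int, float] = {}
    if points is not None:
        for p in points:
            amp_by_idx[p.max_idx] = p.amplitude

    def amp_of(idx: int) -> float:
        return amp_by_idx.get(int(idx), np.inf)

    rr_short = config.short_rr_frac
    rr_long = config.long_rr_frac
    min_rr = 60.0 / config.fhr_max_bpm * fs  # samples
    max_rr = 60.0 / config.fhr_min_bpm * fs

    # --- FP pass: drop the weaker member of implausibly close pairs -------
    rr = np.diff(cand).astype(float)
    med = _running_median(rr, config.median_window_beats)
    keep = np.ones(cand.size, dtype=bool)
    prev = 0  # index of last kept candidate
    for i in range(1, cand.size):
        interval = cand[i] - cand[prev]
        if interval < rr_short * med[min(i - 1, med.size - 1)] or interval < min_rr:
            victim = i if amp_of(cand[i]) <= amp_of(cand[prev]) else prev
            keep[victim] = False
            audit.append({"action": "remove_fp", "index": int(cand[victim]), "rr_samples": int(interval)})
            if victim == prev:
                prev = i
        else:
            prev = i
    cand = cand[keep]
    if cand.size < 2:
        return cand

    # --- FN pass: re-insert the strongest unused point inside long gaps ---
    used = set(int(c) for c in cand)
    unused = (
        sorted((p for p in points if p.max_idx not in used), key=lambda p: p.max_idx)
        if points is not None
        else []
    )
    unused_idx = np.array([p.max_idx for p in unused], dtype=np.int64)
    margin = config.search_margin_ms * fs / 1000.0

    rr = np.diff(cand).astype(float)
    med = _running_median(rr, config.median_window_beats)
    out = [int(cand[0])]
    for i in range(1, cand.size):
        gap = float(cand[i] - cand[i - 1])
        med_rr = med[i - 1]
        if gap > rr_long * med_rr or gap > max_rr:
            expected = cand[i - 1] + med_rr
            # walk the gap, inserting one beat per expected position
            while expected + margin < cand[i] and gap - (expected - cand[i - 1]) > rr_short * med_rr:
                lo = np.searchsorted(unused_idx, int(np.floor(expected - margin)))
                hi = np.searchsorted(unused_idx, int(np.ceil(expected + margin)), side="right")
                if hi > lo:
                    window_pts = unused[lo:hi]
                    best = max(window_pts, key=lambda p: p.amplitude)
                    out.append(int(best.max_idx))
                    audit.append({"action": "insert_fn", "index": int(best.max_idx), "gap_samples": int(gap)})
                    expected = best.max_idx + med_rr
                else:
                    logger.debug("gap at %d: no insertion point found", int(cand[i - 1]))
                    expected += med_rr
            if gap > rr_long * med_rr and len(out) and out[-1] == int(cand[i - 1]):
                logger.debug("long RR gap (%.0f samples) left uncorrected at %d", gap, int(cand[i - 1]))
        out.append(int(cand[i]))
    result = np.unique(np.array(out, dtype=np.int64))
    return result


__all__ = ["RefineConfig", "CorrectionConfig", "refine_fetal_cluster", "correct_fp_fn"]
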