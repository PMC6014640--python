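"""Beat-matching evaluation (Se / PPV / Acc / F1) and FHR series computation.

A detection matches a reference fetal R-wave annotation when it lies
within a fixed tolerance (50 ms by default) of it; the matching is
one-to-one and greedy in reference order. Matched detections are true
detections (TD), unmatched reference beats false negatives (FN), and
unmatched detections false positives (FP). The summary statistics are

    Se  = 100 * TD / (TD + FN)          sensitivity
    PPV = 100 * TD / (TD + FP)          positive predictive value
    Acc = 100 * TD / (TD + FN + FP)     accuracy
    F1  = 100 * 2 TD / (2 TD + FN + FP) F1-measure
        = 2 * PPV * Se / (PPV + Se)     (equivalent form)

The fetal heart rate series is the instantaneous 60/RR in bpm, aligned to
the later beat of each interval, with no smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    """TD/FN/FP counts and percentage metrics for one comparison."""

    total_fqrs: int
    TD: int
    FN: int
    FP: int
    Se: float
    PPV: float
    Acc: float
    F1: float
    tol_ms: float = 50.0

    def rounded(self, decimals: int = 2) -> dict:
        """Metrics rounded half-up, as conventionally tabulated."""
        from decimal import ROUND_HALF_UP, Decimal

        q = Decimal(10) ** -decimals

        def r(x: float) -> float:
            return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))

        return {
            "total_fqrs": self.total_fqrs,
            "TD": self.TD,
            "FN": self.FN,
            "FP": self.FP,
            "Se": r(self.Se),
            "PPV": r(self.PPV),
            "Acc": r(self.Acc),
            "F1": r(self.F1),
        }


@dataclass(frozen=True)
class FhrSeries:
    """Instantaneous fetal heart rate from successive RR intervals."""

    beat_times_s: np.ndarray
    rr_s: np.ndarray
    bpm: np.ndarray


def match_detections(
    detected: AnnotationSet | np.ndarray,
    reference: AnnotationSet | np.ndarray,
    fs: float,
    tol_ms: float = 50.0,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one greedy matching of detections to reference beats.

    Reference beats are visited in order; each is matched to the nearest
    unused detection within ``tol_ms``. Returns ``(TD, FN, FP, pairing)``
    where pairing holds (reference_index, detection_index) sample pairs.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    det = detected.indices if isinstance(detected, AnnotationSet) else np.asarray(detected, dtype=np.int64)
    ref = reference.indices if isinstance(reference, AnnotationSet) else np.asarray(reference, dtype=np.int64)
    tol = tol_ms * fs / 1000.0
    used = np.zeros(det.size, dtype=bool)
    pairing: list[tuple[int, int]] = []
    for r in ref:
        lo = int(np.searchsorted(det, r - tol))
        hi = int(np.searchsorted(det, r + tol, side="right"))
        window = [c for c in range(lo, hi) if not used[c]]
        if not window:
            continue
        best = min(window, key=lambda c: abs(int(det[c]) - int(r)))
        used[best] = True
        pairing.append((int(r), int(det[best])))
    td = len(pairing)
    fn = int(ref.size) - td
    fp = int(det.size) - td
    return td, fn, fp, pairing


def compute_metrics(TD: int, FN: int, FP: int, tol_ms: float = 50.0) -> EvalReport:
    """Se/PPV/Acc/F1 percentages from the three counts.

    ``TD + FN`` (the reference beat count) must be at least 1. A degenerate
    PPV (no detections at all) is reported as 0 with a warning.
    """
    if min(TD, FN, FP) < 0:
        raise ValueError("counts must be >= 0")
    total = TD + FN
    if total == 0:
        raise ValueError("no reference beats: TD + FN == 0")
    se = 100.0 * TD / (TD + FN)
    if TD + FP == 0:
        logger.warning("no detections: PPV undefined, reported as 0")
        ppv = 0.0
    else:
        ppv = 100.0 * TD / (TD + FP)
    acc = 100.0 * TD / (TD + FN + FP)
    f1 = 100.0 * 2.0 * TD / (2.0 * TD + FN + FP) if TD else 0.0
    return EvalReport(total_fqrs=total, TD=TD, FN=FN, FP=FP, Se=se, PPV=ppv, Acc=acc, F1=f1, tol_ms=tol_ms)


def evaluate(
    detected: AnnotationSet | np.ndarray,
    reference: AnnotationSet | np.ndarray,
    fs: float,
    tol_ms: float = 50.0,
) -> EvalReport:
    """Match then score: convenience composition of the two steps above."""
    td, fn, fp, _ = match_detections(detected, reference, fs, tol_ms)
    return compute_metrics(td, fn, fp, tol_ms)


def fhr_series(detected: AnnotationSet | np.ndarray, fs: float) -> FhrSeries:
    """Instantaneous FHR in bpm from at least 2 detected beats."""
    idx = detected.indices if isinstance(detected, AnnotationSet) else np.asarray(detected, dtype=np.int64)
    if idx.size < 2:
        raise ValueError("need at least 2 beats for an FHR series")
    times = idx / fs
    rr = np.diff(times)
    return FhrSeries(beat_times_s=times, rr_s=rr, bpm=60.0 / rr)


__all__ = [
    "EvalReport",
    "FhrSeries",
    "match_detections",
    "compute_metrics",
    "evaluate",
    "fhr_series",
]
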