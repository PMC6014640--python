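"""One-pass DWT denoising that removes baseline wander and noise together.

The signal is decomposed to depth ``L`` with an orthogonal wavelet
(default ``db6``). The approximation coefficients at level ``L`` — which
carry the DC offset and slow baseline wander — are replaced by zeros. The
detail coefficients at the finest levels ``1..M`` are shrunk with the
universal threshold ``sigma * sqrt(2 ln N)``, where a single noise level
``sigma = median(|d1|) / 0.6745`` is estimated once from the level-1
details and reused at all thresholded levels ("single rescaling").
Details at levels ``M+1..L``, which carry the QRS energy at typical ECG
sampling rates, pass through unchanged, and the signal is reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .signal_io import EcgRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseConfig:
    """Wavelet preprocessing parameters.

    Defaults follow the standard abdominal-ECG configuration: ``db6``,
    depth ``L = 7``, the ``M = 3`` finest detail levels thresholded,
    universal threshold with single rescaling, soft thresholding.
    """

    wavelet: str = "db6"
    L: int = 7
    M: int = 3
    threshold_rule: str = "soft"

    def __post_init__(self) -> None:
        if not 1 <= self.M < self.L:
            raise ValueError(f"need 1 <= M < L, got M={self.M}, L={self.L}")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError(f"threshold_rule must be 'soft' or 'hard', got {self.threshold_rule!r}")
        try:
            w = pywt.Wavelet(self.wavelet)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet {self.wavelet!r}") from exc
        if not w.orthogonal:
            raise ValueError(f"wavelet {self.wavelet!r} is not orthogonal")


def universal_threshold(detail_coeffs_level1: np.ndarray, n_total: int) -> float:
    """Universal threshold ``sigma * sqrt(2 ln n_total)`` with the noise
    level estimated from the finest detail coefficients as
    ``sigma = median(|d1|) / 0.6745`` (the MAD estimator of a Gaussian sd).

    ``n_total`` is the full signal length, not the per-level coefficient
    count, matching common wavelet-shrinkage toolbox semantics.
    """
    d1 = np.asarray(detail_coeffs_level1, dtype=float)
    if d1.size == 0:
        raise ValueError("empty detail coefficients")
    sigma = float(np.median(np.abs(d1))) / 0.6745
    return sigma * np.sqrt(2.0 * np.log(n_total))


def denoise(record: EcgRecord, config: DenoiseConfig = DenoiseConfig()) -> EcgRecord:
    """Return a denoised copy of ``record`` with identical length and fs.

    Signals too short for the configured depth are processed at the
    largest feasible depth with a warning (M is reduced alongside if
    needed). Boundary handling uses symmetric (half-point) extension.
    """
    x = record.samples
    level = config.L
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(config.wavelet).dec_len)
    if max_level < 1:
        raise ValueError(f"signal of length {x.size} too short for wavelet {config.wavelet!r}")
    if level > max_level:
        logger.warning(
            "record %s: length %d supports depth %d < requested L=%d; using %d",
            record.record_id, x.size, max_level, level, max_level,
        )
        level = max_level
    m = min(config.M, level - 1) if level > 1 else 0

    coeffs = pywt.wavedec(x, config.wavelet, mode="symmetric", level=level)
    coeffs[0] = np.zeros_like(coeffs[0])  # approximations at depth L: DC + wander
    if m >= 1:
        thr = universal_threshold(coeffs[-1], x.size)
        if thr > 0:  # a zero threshold (noise-free signal) is a no-op
            for i in range(1, m + 1):  # coeffs[-1] is level 1, coeffs[-m] is level m
                coeffs[-i] = pywt.threshold(coeffs[-i], thr, mode=config.threshold_rule)
    y = pywt.waverec(coeffs, config.wavelet, mode="symmetric")[: x.size]
    return EcgRecord(record_id=record.record_id, channel=record.channel, fs=record.fs, samples=y)


__all__ = ["DenoiseConfig", "universal_threshold", "denoise"]
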